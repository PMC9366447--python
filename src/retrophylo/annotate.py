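"""SINE copy detection and candidate-locus selection.

Detects copies of SINE consensus sequences in genomes with a seeded local
aligner (exact k-mer seeds extended by gapped local alignment) or ingests
RepeatMasker ``.out`` files, then applies the diagnostic-locus filters:
nearly full-length elements (strictly under 10 nt truncation at either end)
with TE-sparse flanks (under 50% repeat coverage in each 500-nt flank).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._seq import KmerIndex, cluster_seed_hits, local_align, revcomp
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class RepeatAnnotation:
    """One detected repeat copy, 0-based half-open genome coordinates.

    Truncations are measured in consensus coordinates and strand-normalized,
    so ``truncation_5p`` always refers to the consensus 5' end.
    """

    species: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    divergence: float
    truncation_5p: int = 0
    truncation_3p: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0,1]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class CandidateLocus:
    """A filter-passing element with strand-normalized adjacent flanks."""

    locus_id: str
    reference_species: str
    annotation: RepeatAnnotation
    left_flank: str   # 5' of the element in element orientation
    right_flank: str
    flank_te_fraction: float  # max of the two per-flank repeat coverages


def scan_genome(
    sequences: dict[str, str],
    library: dict[str, str],
    min_identity: float = 0.80,
    species: str = "genome",
    k: int = 12,
) -> list[RepeatAnnotation]:
    """Detect library consensus copies on both strands of a genome.

    Every reported hit aligns to its consensus at >= ``min_identity`` over the
    reported span. Overlapping hits to the same family are merged, keeping the
    higher-identity (then leftmost) one.
    """
    if not library:
        raise ValueError("element library is empty")
    if not sequences or all(len(s) == 0 for s in sequences.values()):
        raise ValueError("genome is empty")
    if not 0.5 < min_identity <= 1.0:
        raise ValueError("min_identity must lie in (0.5, 1]")
    for fam, cons in library.items():
        if len(cons) < 50:
            raise ValueError(f"consensus {fam!r} shorter than 50 nt")

    index = KmerIndex(sequences, k)
    raw: list[RepeatAnnotation] = []
    for family in sorted(library):
        cons = library[family].upper()
        for strand in "+-":
            query = cons if strand == "+" else revcomp(cons)
            for contig, pairs in index.hits(query).items():
                seq = sequences[contig]
                for diag, gmin, gmax in cluster_seed_hits(
                    pairs, band=24, max_gap=len(query)
                ):
                    ws = max(0, min(diag, gmin) - 30)
                    we = min(len(seq), max(diag + len(query), gmax + k) + 30)
                    aln = local_align(query, seq[ws:we])
                    if aln is None or aln.length < 30:
                        continue
                    if aln.identity < min_identity:
                        continue
                    if strand == "+":
                        t5, t3 = aln.query_start, len(cons) - aln.query_end
                    else:
                        t5, t3 = len(cons) - aln.query_end, aln.query_start
                    raw.append(
                        RepeatAnnotation(
                            species=species,
                            contig=contig,
                            start=ws + aln.target_start,
                            end=ws + aln.target_end,
                            strand=strand,
                            family=family,
                            divergence=round(1.0 - aln.identity, 6),
                            truncation_5p=t5,
                            truncation_3p=t3,
                        )
                    )
    return _merge_same_family(raw)


def _merge_same_family(annotations: list[RepeatAnnotation]) -> list[RepeatAnnotation]:
    """Drop same-family hits overlapping a better one (identity, then leftmost)."""
    kept: list[RepeatAnnotation] = []
    by_key: dict[tuple[str, str], list[RepeatAnnotation]] = {}
    for ann in annotations:
        by_key.setdefault((ann.contig, ann.family), []).append(ann)
    for group in by_key.values():
        group.sort(key=lambda a: (a.divergence, a.start))
        chosen: list[RepeatAnnotation] = []
        for ann in group:
            if all(ann.end <= c.start or ann.start >= c.end for c in chosen):
                chosen.append(ann)
        kept.extend(chosen)
    kept.sort(key=lambda a: (a.contig, a.start, a.family))
    return kept


def read_repeatmasker_out(path, species: str = "query") -> list[RepeatAnnotation]:
    """Read a RepeatMasker ``.out`` file into annotations.

    1-based inclusive query coordinates become 0-based half-open; ``C``
    orientation maps to ``-`` with the repeat-position triple read
    right-to-left, and ``(left)`` parentheticals give the 3' truncation.
    Malformed rows are skipped with a warning.
    """
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0] in ("SW", "score") or not fields[0][0].isdigit():
                continue
            try:
                div = float(fields[1]) / 100.0
                contig = fields[4]
                qbeg, qend = int(fields[5]), int(fields[6])
                orient = fields[8]
                family = fields[9]
                r1, r2, r3 = fields[11], fields[12], fields[13]
                if orient == "+":
                    rbeg, rend, rleft = int(r1), int(r2), int(r3.strip("()"))
                elif orient in ("C", "-"):
                    rleft, rend, rbeg = int(r1.strip("()")), int(r2), int(r3)
                else:
                    raise ValueError(f"bad orientation {orient!r}")
                if qbeg < 1 or qend < qbeg or rbeg < 1:
                    raise ValueError("inconsistent coordinates")
                out.append(
                    RepeatAnnotation(
                        species=species,
                        contig=contig,
                        start=qbeg - 1,
                        end=qend,
                        strand="+" if orient == "+" else "-",
                        family=family,
                        divergence=min(div, 1.0),
                        truncation_5p=rbeg - 1,
                        truncation_3p=rleft,
                    )
                )
            except (ValueError, IndexError) as exc:
                logger.warning("skipping malformed .out row %d: %s", lineno, exc)
    return out


def write_annotations(annotations: list[RepeatAnnotation], path) -> None:
    """Write annotations as a TSV mirroring the ``.out`` content (round-trippable)."""
    cols = ("species", "contig", "start", "end", "strand", "family",
            "divergence", "truncation_5p", "truncation_3p")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            fh.write("\t".join(str(getattr(a, c)) for c in cols) + "\n")


def read_annotations(path) -> list[RepeatAnnotation]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                RepeatAnnotation(
                    species=rec["species"], contig=rec["contig"],
                    start=int(rec["start"]), end=int(rec["end"]),
                    strand=rec["strand"], family=rec["family"],
                    divergence=float(rec["divergence"]),
                    truncation_5p=int(rec["truncation_5p"]),
                    truncation_3p=int(rec["truncation_3p"]),
                )
            )
    return out


def _interval_coverage(intervals: list[tuple[int, int]], lo: int, hi: int) -> float:
    """Fraction of [lo, hi) covered by the union of the intervals."""
    if hi <= lo:
        return 0.0
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if e > lo and s < hi
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / (hi - lo)


def select_candidate_loci(
    annotations: list[RepeatAnnotation],
    sequences: dict[str, str],
    config: PipelineConfig | None = None,
    families: set[str] | None = None,
) -> list[CandidateLocus]:
    """Apply the diagnostic-locus filters and extract strand-normalized flanks.

    Keeps elements with both truncations strictly under ``max_truncation`` and
    both ``flank_len`` flanks under ``te_density_max`` repeat coverage
    (coverage by annotations of any family); loci closer than ``flank_len``
    to a contig end are rejected.
    """
    cfg = config or PipelineConfig()
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        by_contig.setdefault(a.contig, []).append((a.start, a.end))

    out: list[CandidateLocus] = []
    for ann in sorted(annotations, key=lambda a: (a.contig, a.start)):
        if families is not None and ann.family not in families:
            continue
        if ann.contig not in sequences:
            raise KeyError(f"contig {ann.contig!r} absent from genome")
        if ann.truncation_5p >= cfg.max_truncation:
            continue
        if ann.truncation_3p >= cfg.max_truncation:
            continue
        seq = sequences[ann.contig]
        if ann.start < cfg.flank_len or ann.end + cfg.flank_len > len(seq):
            continue
        others = by_contig[ann.contig]
        left_cov = _interval_coverage(others, ann.start - cfg.flank_len, ann.start)
        right_cov = _interval_coverage(others, ann.end, ann.end + cfg.flank_len)
        # the element itself lies outside both flank windows, so its own
        # interval never contributes to coverage
        if left_cov >= cfg.te_density_max or right_cov >= cfg.te_density_max:
            continue
        left = seq[ann.start - cfg.flank_len : ann.start]
        right = seq[ann.end : ann.end + cfg.flank_len]
        if ann.strand == "-":
            left, right = revcomp(right), revcomp(left)
        out.append(
            CandidateLocus(
                locus_id=f"{ann.species}|{ann.contig}|{ann.start}-{ann.end}",
                reference_species=ann.species,
                annotation=ann,
                left_flank=left,
                right_flank=right,
                flank_te_fraction=max(left_cov, right_cov),
            )
        )
    return out
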