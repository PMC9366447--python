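"""Flanking-sequence analyses: concatenation, quartet concordance, gap filters.

The sequence counterpart of the presence/absence matrix: ~1 kb of flank per
marker locus is concatenated within each hypothesis group, and support for
the three quartet splits is measured by exhaustive four-taxon site-pattern
counting (site concordance) and per-locus plurality votes (gene
concordance). Random-locus alignments pass through the stated gap rules
(single gap run over 25% of the alignment, or 50% gap cells in total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")


@dataclass
class QuartetSupport:
    """Site- or locus-level support for the three quartet splits.

    Split order: (g1,g2|g3,g4), (g1,g3|g2,g4), (g1,g4|g2,g3) over the group
    order supplied by the caller.
    """

    counts: tuple[int, int, int]
    total_informative: int
    cf: tuple[float, float, float] | None

    @property
    def empty(self) -> bool:
        return self.total_informative == 0


@dataclass
class ConcatenatedAlignment:
    """A concatenated multi-locus alignment with a partition table."""

    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)  # id, start, end

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def concatenate_flanks(
    locus_alignments: dict[str, dict[str, str]],
    taxa: list[str],
) -> ConcatenatedAlignment:
    """Concatenate per-locus flank alignments over a fixed taxon set.

    Loci missing any taxon (or with ragged rows) are dropped with a warning;
    partition boundaries of the kept loci are recorded (0-based half-open).
    """
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for locus_id in sorted(locus_alignments):
        aln = locus_alignments[locus_id]
        if any(t not in aln for t in taxa):
            logger.warning("locus %s missing a taxon; dropped", locus_id)
            continue
        lens = {len(aln[t]) for t in taxa}
        if len(lens) != 1:
            logger.warning("locus %s rows are ragged; dropped", locus_id)
            continue
        n = lens.pop()
        for t in taxa:
            parts[t].append(aln[t])
        partitions.append((locus_id, pos, pos + n))
        pos += n
    return ConcatenatedAlignment(
        sequences={t: "".join(parts[t]) for t in taxa}, partitions=partitions
    )


def _site_vote(bases: tuple[str, str, str, str]) -> int | None:
    """Which split a quartet site supports: 0=12|34, 1=13|24, 2=14|23."""
    if any(b not in _DNA for b in bases):
        return None
    a, b, c, d = bases
    if a == b and c == d and a != c:
        return 0
    if a == c and b == d and a != b:
        return 1
    if a == d and b == c and a != b:
        return 2
    return None


def quartet_site_concordance(
    alignment: dict[str, str],
    grouping: list[list[str]] | list[str],
    seed: int = 0,
) -> QuartetSupport:
    """Count parsimony-informative quartet site patterns per split.

    ``grouping`` is four taxa or four disjoint taxon groups (ordered); with
    groups of several taxa, one representative per group is sampled per site
    with a fixed seed. Gapped/ambiguous sites are excluded.
    """
    groups = [[g] if isinstance(g, str) else list(g) for g in grouping]
    if len(groups) != 4:
        raise ValueError("need exactly 4 taxa or taxon groups")
    flat = [t for g in groups for t in g]
    if len(set(flat)) != len(flat):
        raise ValueError("groups must be disjoint")
    for t in flat:
        if t not in alignment:
            raise KeyError(f"taxon {t!r} missing from alignment")
    lens = {len(alignment[t]) for t in flat}
    if len(lens) != 1:
        raise ValueError("ragged alignment")
    ncol = lens.pop()
    rng = np.random.default_rng(seed)
    counts = [0, 0, 0]
    for j in range(ncol):
        reps = tuple(
            alignment[g[0] if len(g) == 1 else g[int(rng.integers(len(g)))]][j].upper()
            for g in groups
        )
        v = _site_vote(reps)
        if v is not None:
            counts[v] += 1
    total = sum(counts)
    cf = tuple(c / total for c in counts) if total else None
    return QuartetSupport(counts=tuple(counts), total_informative=total, cf=cf)


def gene_concordance(
    locus_alignments: dict[str, dict[str, str]],
    grouping: list[list[str]] | list[str],
    seed: int = 0,
) -> QuartetSupport:
    """Per-locus plurality votes over the three quartet splits (gCF).

    Each locus votes for the split holding the strict plurality of its
    informative sites and abstains on ties or zero informative sites; the
    concordance factors are votes over voting loci.
    """
    if not locus_alignments:
        raise ValueError("need at least one locus alignment")
    votes = [0, 0, 0]
    for locus_id in sorted(locus_alignments):
        sup = quartet_site_concordance(locus_alignments[locus_id], grouping, seed=seed)
        if sup.empty:
            continue
        top = max(sup.counts)
        winners = [i for i, c in enumerate(sup.counts) if c == top]
        if len(winners) == 1:
            votes[winners[0]] += 1
    total = sum(votes)
    cf = tuple(v / total for v in votes) if total else None
    return QuartetSupport(counts=tuple(votes), total_informative=total, cf=cf)


@dataclass
class FilterResult:
    kept: bool
    reason: str | None = None


def filter_random_locus_alignment(
    alignment: dict[str, str],
    max_gap_run_frac: float = 0.25,
    max_total_gap_frac: float = 0.50,
) -> FilterResult:
    """Apply the stated gap-exclusion rules to one locus alignment.

    Rejects when any single sequence has a contiguous gap run longer than
    ``max_gap_run_frac`` of the alignment length (reason ``gap_run``) or when
    gaps make up at least ``max_total_gap_frac`` of all cells (reason
    ``total_gaps``); otherwise the alignment is kept unchanged.
    """
    if not alignment:
        raise ValueError("empty alignment")
    lens = {len(s) for s in alignment.values()}
    if len(lens) != 1:
        raise ValueError("ragged alignment (unequal row lengths)")
    ncol = lens.pop()
    if ncol == 0:
        raise ValueError("zero-length alignment")
    for seq in alignment.values():
        run = best = 0
        for ch in seq:
            run = run + 1 if ch == "-" else 0
            best = max(best, run)
        if best > max_gap_run_frac * ncol:
            return FilterResult(kept=False, reason="gap_run")
    cells = ncol * len(alignment)
    gaps = sum(s.count("-") for s in alignment.values())
    if gaps >= max_total_gap_frac * cells:
        return FilterResult(kept=False, reason="total_gaps")
    return FilterResult(kept=True)


def write_fasta_alignment(alignment: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in alignment:
            fh.write(f">{name}\n{alignment[name]}\n")


def write_partition_table(partitions: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tstart\tend\n")
        for locus_id, s, e in partitions:
            fh.write(f"{locus_id}\t{s}\t{e}\n")
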