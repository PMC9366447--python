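"""Presence/absence (1/0) marker matrix: construction, export, Dollo support.

The matrix encodes validated diagnostic insertions as irreversible binary
characters (gained once, never precisely excised). Exports to NEXUS
(datatype=standard, symbols "01", missing '?'), relaxed PHYLIP and TSV feed
external split-network and Bayesian tools; internal split support comes from
a column bootstrap under gain-once character logic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .validate import DiagnosticMarker

MISSING = "?"


@dataclass
class BinaryMatrix:
    """Taxa x markers matrix with entries in {0, 1, ?}."""

    taxa: list[str]
    marker_ids: list[str]
    entries: np.ndarray  # dtype '<U1', shape (len(taxa), len(marker_ids))

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype="<U1")
        if self.entries.shape != (len(self.taxa), len(self.marker_ids)):
            raise ValueError("entry dimensions inconsistent with taxa/markers")
        bad = set(self.entries.ravel()) - {"0", "1", MISSING}
        if bad:
            raise ValueError(f"invalid matrix symbols: {bad}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.taxa, columns=self.marker_ids)

    def column(self, marker_id: str) -> dict[str, str]:
        j = self.marker_ids.index(marker_id)
        return {t: self.entries[i, j] for i, t in enumerate(self.taxa)}


def build_matrix(
    markers: list[DiagnosticMarker],
    taxa: list[str],
    ingroup: list[str] | None = None,
) -> BinaryMatrix:
    """Assemble the 1/0 matrix from validated markers.

    1 = present, 0 = absent, ? = not scored. Column order is stable by
    locus id; every column must segregate (>= 1 one and >= 1 zero) among the
    ingroup taxa (all taxa when no ingroup is given).
    """
    ids = [m.locus_id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids")
    order = sorted(range(len(markers)), key=lambda i: ids[i])
    check = ingroup if ingroup is not None else taxa
    cols = []
    kept_ids = []
    for i in order:
        m = markers[i]
        col = []
        for t in taxa:
            st = m.states.get(t)
            col.append("1" if st == "present" else "0" if st == "absent" else MISSING)
        vals = {col[taxa.index(t)] for t in check}
        if "1" not in vals or "0" not in vals:
            raise ValueError(
                f"marker {m.locus_id} does not segregate among ingroup taxa"
            )
        cols.append(col)
        kept_ids.append(m.locus_id)
    entries = (np.array(cols, dtype="<U1").T if cols
               else np.empty((len(taxa), 0), dtype="<U1"))
    return BinaryMatrix(taxa=list(taxa), marker_ids=kept_ids, entries=entries)


def _nexus_name(name: str) -> str:
    return re.sub(r"\s+", "_", name.strip())


def write_matrix(matrix: BinaryMatrix, path, fmt: str = "nexus") -> None:
    """Write the matrix as NEXUS, relaxed PHYLIP or TSV (byte-stable)."""
    if matrix.shape[1] == 0:
        raise ValueError("refusing to write an empty matrix")
    ntax, nchar = matrix.shape
    with open(path, "w") as fh:
        if fmt == "nexus":
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={ntax} NCHAR={nchar};\n")
            fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
            fh.write("  MATRIX\n")
            width = max(len(_nexus_name(t)) for t in matrix.taxa) + 2
            for i, t in enumerate(matrix.taxa):
                fh.write(f"    {_nexus_name(t):<{width}}"
                         f"{''.join(matrix.entries[i])}\n")
            fh.write("  ;\nEND;\n")
        elif fmt == "phylip":
            fh.write(f"{ntax} {nchar}\n")
            for i, t in enumerate(matrix.taxa):
                fh.write(f"{_nexus_name(t)}  {''.join(matrix.entries[i])}\n")
        elif fmt == "tsv":
            fh.write("taxon\t" + "\t".join(matrix.marker_ids) + "\n")
            for i, t in enumerate(matrix.taxa):
                fh.write(t + "\t" + "\t".join(matrix.entries[i]) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_matrix(path, fmt: str = "nexus") -> BinaryMatrix:
    """Read a matrix previously written by :func:`write_matrix`."""
    with open(path) as fh:
        text = fh.read()
    if fmt == "nexus":
        m = re.search(r"MATRIX\s*\n(.*?)\n\s*;", text, re.S | re.I)
        if m is None:
            raise ValueError("no MATRIX block found")
        taxa, rows = [], []
        for line in m.group(1).strip().splitlines():
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(list(seq.strip()))
        ids = [f"c{j}" for j in range(len(rows[0]))]
        return BinaryMatrix(taxa, ids, np.array(rows, dtype="<U1"))
    if fmt == "phylip":
        lines = text.strip().splitlines()
        taxa, rows = [], []
        for line in lines[1:]:
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(list(seq.strip()))
        ids = [f"c{j}" for j in range(len(rows[0]))]
        return BinaryMatrix(taxa, ids, np.array(rows, dtype="<U1"))
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return BinaryMatrix(list(df.index), list(df.columns),
                            df.to_numpy(dtype="<U1"))
    raise ValueError(f"unknown format {fmt!r}")


def _column_split(
    col: dict[str, str], lineage_map: dict[str, str], splits: list[frozenset[str]],
    outgroup_lineage: str,
) -> frozenset[str] | None:
    """The split a column supports under gain-once logic, or None.

    A column votes for the split whose two lineages are consistently 1 while
    the remaining ingroup lineage and the outgroup are consistently 0.
    """
    by_lineage: dict[str, set[str]] = {}
    for sp, v in col.items():
        by_lineage.setdefault(lineage_map[sp], set()).add(v)
    states = {}
    for lin, vals in by_lineage.items():
        vals = vals - {MISSING}
        if len(vals) != 1:
            return None
        states[lin] = vals.pop()
    if states.get(outgroup_lineage, "0") != "0":
        return None
    present = frozenset(l for l, v in states.items()
                        if v == "1" and l != outgroup_lineage)
    return present if present in splits else None


def dollo_support_bootstrap(
    matrix: BinaryMatrix,
    lineage_map: dict[str, str],
    reps: int = 1000,
    seed: int = 0,
    outgroup_lineage: str = "outgroup",
) -> dict[str, float]:
    """Column-bootstrap support for the three competing two-lineage splits.

    Each column is assigned to the split it supports under irreversible
    (gain-once) character logic; columns are resampled with replacement and
    a split scores a replicate when it holds the strict plurality of
    supporting columns. Returns percentages per split plus 'unresolved'.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    lineages = sorted({l for l in lineage_map.values() if l != outgroup_lineage})
    if len(lineages) != 3:
        raise ValueError("need exactly 3 ingroup lineages")
    l1, l2, l3 = lineages
    splits = [frozenset((l1, l2)), frozenset((l1, l3)), frozenset((l2, l3))]
    labels = {s: "+".join(sorted(s)) for s in splits}

    votes = []
    for mid in matrix.marker_ids:
        s = _column_split(matrix.column(mid), lineage_map, splits, outgroup_lineage)
        if s is not None:
            votes.append(splits.index(s))
    if not votes:
        raise ValueError("matrix has no informative columns")
    votes = np.array(votes)
    rng = np.random.default_rng(seed)
    wins = np.zeros(3, dtype=int)
    unresolved = 0
    for _ in range(reps):
        resampled = votes[rng.integers(0, votes.size, size=votes.size)]
        counts = np.bincount(resampled, minlength=3)
        top = counts.max()
        winners = np.nonzero(counts == top)[0]
        if winners.size == 1:
            wins[winners[0]] += 1
        else:
            unresolved += 1
    out = {labels[s]: 100.0 * wins[i] / reps for i, s in enumerate(splits)}
    out["unresolved"] = 100.0 * unresolved / reps
    return out


def position_dispersion_summary(
    positions: list[tuple[str, int]],
    contig_lengths: dict[str, int],
) -> dict:
    """Chi-square goodness of fit of marker counts against contig lengths.

    Expected counts are proportional to contig length; contigs with expected
    count < 1 are pooled into one bin for stability. Returns the statistic,
    degrees of freedom, p-value and the per-contig observed counts.
    """
    if any(l <= 0 for l in contig_lengths.values()):
        raise ValueError("contig lengths must be > 0")
    known = [c for c, _ in positions if c in contig_lengths]
    if not known:
        raise ValueError("no markers fall on listed contigs")
    n = len(known)
    total_len = sum(contig_lengths.values())
    observed: dict[str, int] = {c: 0 for c in contig_lengths}
    for c in known:
        observed[c] += 1
    exp = {c: n * contig_lengths[c] / total_len for c in contig_lengths}
    big = [c for c in contig_lengths if exp[c] >= 1.0]
    small = [c for c in contig_lengths if exp[c] < 1.0]
    obs_arr = [observed[c] for c in big]
    exp_arr = [exp[c] for c in big]
    if small:
        obs_arr.append(sum(observed[c] for c in small))
        exp_arr.append(sum(exp[c] for c in small))
    obs_arr = np.array(obs_arr, dtype=float)
    exp_arr = np.array(exp_arr, dtype=float)
    stat, p = sps.chisquare(obs_arr, exp_arr)
    return {
        "statistic": float(stat),
        "df": int(obs_arr.size - 1),
        "p_value": float(p),
        "counts": observed,
        "pooled_contigs": small,
    }
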