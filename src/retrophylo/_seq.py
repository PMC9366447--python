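"""Low-level nucleotide utilities: encoding, k-mer indexing, pairwise alignment.

These helpers back the internal repeat annotator and the flank-anchoring
ortholog screen. Exact k-mer seeds are found with vectorised integer k-mer
codes; candidate regions are then refined with proper pairwise alignment
(scikit-bio local alignment for coordinates/identity, edlib for fast
semiglobal edit-distance checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from skbio.alignment import pair_align

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# A..Z -> 0..3 for ACGT, 4 otherwise
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (keeps N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A,C,G,T -> 0..3; anything else 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers; -1 where a non-ACGT base falls.

    Codes are base-4 big-endian over the window, so k <= 31 fits in int64.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    enc = encode(seq).astype(np.int64)
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        codes = codes * 4 + enc[j : j + n]
        bad |= enc[j : j + n] > 3
    codes[bad] = -1
    return codes


class KmerIndex:
    """Sorted k-mer index over the contigs of one genome.

    Supports exact-match position lookup for query k-mers; used both for
    SINE-consensus seeding and for flank anchoring.
    """

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self.contigs = list(sequences)
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        self._sorted: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            codes = kmer_codes(seq, k)
            order = np.argsort(codes, kind="stable")
            self._codes[name] = codes
            self._order[name] = order
            self._sorted[name] = codes[order]

    def hits(self, query: str) -> dict[str, list[tuple[int, int]]]:
        """Exact-match positions per contig.

        Returns {contig: [(genome_pos, query_offset), ...]} for every k-mer of
        the query found in the contig.
        """
        qcodes = kmer_codes(query, self.k)
        valid = np.nonzero(qcodes >= 0)[0]
        out: dict[str, list[tuple[int, int]]] = {}
        for name in self.contigs:
            skey = self._sorted[name]
            if skey.size == 0:
                continue
            lo = np.searchsorted(skey, qcodes[valid], side="left")
            hi = np.searchsorted(skey, qcodes[valid], side="right")
            pairs = []
            order = self._order[name]
            for qoff, a, b in zip(valid, lo, hi):
                if b > a:
                    for gpos in order[a:b]:
                        pairs.append((int(gpos), int(qoff)))
            if pairs:
                pairs.sort()
                out[name] = pairs
        return out


@dataclass
class LocalAlignment:
    """Coordinates and quality of a best local alignment of query vs target."""

    query_start: int
    query_end: int  # half-open
    target_start: int
    target_end: int  # half-open
    score: float
    matches: int
    length: int  # aligned columns

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


def local_align(query: str, target: str) -> LocalAlignment | None:
    """Best local alignment (match 2, mismatch -3, gap open 5 extend 2)."""
    if not query or not target:
        return None
    res = pair_align(
        query, target, mode="local", sub_score=(2.0, -3.0), gap_cost=(5.0, 2.0)
    )
    if not res.paths:
        return None
    path = res.paths[0]
    (qs, qe), (ts, te) = path.ranges
    # walk the path to count matched columns
    matches = 0
    length = 0
    qi, ti = qs, ts
    for state, seg in zip(path.states[0], path.lengths):
        if state == 0:  # aligned columns
            for j in range(seg):
                length += 1
                if query[qi + j].upper() == target[ti + j].upper():
                    matches += 1
            qi += seg
            ti += seg
        elif state == 1:  # gap in query -> consumes target
            ti += seg
            length += seg
        else:  # gap in target -> consumes query
            qi += seg
            length += seg
    return LocalAlignment(int(qs), int(qe), int(ts), int(te), float(res.score), matches, length)


def semiglobal_locate(query: str, target: str, max_ed: int = -1):
    """Locate query inside target (edlib HW); returns (start, end, edit_distance) or None."""
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    return int(s), int(e) + 1, int(res["editDistance"])


def cluster_seed_hits(
    pairs: list[tuple[int, int]], band: int = 24, max_gap: int = 400
) -> list[tuple[int, int, int]]:
    """Group (genome_pos, query_offset) seed hits into candidate loci.

    Hits are clustered on the alignment diagonal (genome_pos - query_offset)
    within ``band`` nt, splitting clusters at genomic gaps over ``max_gap``.
    Returns (diag_min, gpos_min, gpos_max) per cluster, sorted by position.
    """
    if not pairs:
        return []
    diags = sorted((g - q, g) for g, q in pairs)
    clusters: list[tuple[int, int, int]] = []
    cur_d0, cur_gmin, cur_gmax = diags[0][0], diags[0][1], diags[0][1]
    cur_dmax = cur_d0
    for d, g in diags[1:]:
        if d - cur_dmax <= band:
            cur_dmax = d
            cur_gmin = min(cur_gmin, g)
            cur_gmax = max(cur_gmax, g)
        else:
            clusters.append((cur_d0, cur_gmin, cur_gmax))
            cur_d0, cur_dmax, cur_gmin, cur_gmax = d, d, g, g
    clusters.append((cur_d0, cur_gmin, cur_gmax))
    # split clusters with large genomic gaps
    out: list[tuple[int, int, int]] = []
    by_diag: dict[tuple[int, int, int], list[int]] = {}
    for c in clusters:
        lo, hi = c[0] - band, c[0] + band
        gs = sorted(g for g, q in pairs if lo <= g - q <= hi)
        runs: list[list[int]] = [[gs[0]]]
        for g in gs[1:]:
            if g - runs[-1][-1] <= max_gap:
                runs[-1].append(g)
            else:
                runs.append([g])
        for r in runs:
            out.append((c[0], r[0], r[-1]))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
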