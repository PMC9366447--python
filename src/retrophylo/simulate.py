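"""Synthetic genome evolution for retrophylogenomic pipelines.

Generates four-taxon genome sets — topology ((L1,L2),L3),O with a short
internal branch — together with a ground-truth table of SINE insertion
events. Insertions on the internal branch sort across the L1/L2/L3 split
under the standard neutral gene-tree discordance model: an internal-branch
event of age tau (coalescent units) fixes in the concordant pattern {L1,L2}
with probability 1 - (2/3)e^(-tau) and in each conflicting pattern ({L1,L3},
{L2,L3}) with probability (1/3)e^(-tau). An optional ``hybrid_fraction``
reroutes internal-branch events to one fixed conflicting pattern, creating
the asymmetric signal a hybridization test detects.

Every insertion creates an 8–30 nt target-site duplication; a configurable
fraction of events is 5'-truncated to exercise the downstream "nearly
full-length" filter. Substitutions are applied per branch under a uniform
single-nucleotide model with no indels, so flank orthology stays exact and
truth coordinates are known per species (0-based, half-open).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

BASES = np.array(list("ACGT"))

#: branch labels of the rooted 4-taxon tree; "internal" is the (L1,L2) stem
TERMINAL_BRANCHES = ("L1", "L2", "L3", "O")
INTERNAL_BRANCH = "internal"


def _parse_topology(topology: str) -> tuple[str, str, str, str]:
    """Return (cherry_a, cherry_b, third, outgroup) from a newick-like string."""
    nwk = topology.strip().rstrip(";") + ";"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) != 4 or len(set(leaves)) != 4:
        raise ValueError("topology must have exactly 4 distinct leaves")
    # find the cherry: internal node with exactly two leaf children
    root_children = tree.seed_node.child_nodes()
    cherry = None
    outgroup = None
    for nd in tree.preorder_node_iter():
        kids = nd.child_nodes()
        if kids and all(k.is_leaf() for k in kids) and len(kids) == 2:
            cherry = tuple(k.taxon.label for k in kids)
            break
    if cherry is None:
        raise ValueError("topology must contain a two-leaf cherry ((a,b),c),o")
    # outgroup = the leaf attached closest to the root
    for nd in root_children:
        if nd.is_leaf():
            outgroup = nd.taxon.label
    if outgroup is None:
        raise ValueError("outgroup leaf must attach at the root")
    third = next(l for l in leaves if l not in cherry and l != outgroup)
    return cherry[0], cherry[1], third, outgroup


@dataclass
class SpeciesTreeSpec:
    """Study design for the simulated four-taxon system.

    Parameters
    ----------
    topology : str
        Rooted newick-like description with four leaves, e.g.
        ``"(((L1,L2),L3),O)"``.
    tau : float
        Internal-branch length in coalescent units (>= 0). Default 0.451, the
        value at which the discordance closed form reproduces a ~57.5/21.2/21.2
        pattern split.
    branch_sub_rate : dict
        Expected substitutions per site on each branch
        (keys: L1, L2, L3, O, internal).
    insertion_counts : dict
        Relative expected numbers of insertion events per branch; normalised
        to a sampling distribution over branches.
    hybrid_fraction : float
        Proportion of internal-branch events rerouted to ``hybrid_target``
        (one fixed conflicting pattern), default 0.
    truncated_fraction : float
        Fraction of events given a 5' truncation of 11–100 nt, exercising the
        <10 nt truncation filter downstream.
    """

    topology: str = "(((L1,L2),L3),O)"
    tau: float = 0.451
    branch_sub_rate: dict[str, float] = field(
        default_factory=lambda: {b: 0.01 for b in (*TERMINAL_BRANCHES, INTERNAL_BRANCH)}
    )
    insertion_counts: dict[str, float] = field(
        default_factory=lambda: {
            INTERNAL_BRANCH: 0.6, "L1": 0.1, "L2": 0.1, "L3": 0.1, "O": 0.1}
    )
    hybrid_fraction: float = 0.0
    hybrid_target: str = "conflict_13"  # {cherry_a, third}; or "conflict_23"
    truncated_fraction: float = 0.10

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0 <= self.hybrid_fraction <= 1:
            raise ValueError("hybrid_fraction must lie in [0,1]")
        if any(r < 0 for r in self.branch_sub_rate.values()):
            raise ValueError("substitution rates must be >= 0")
        if any(c < 0 for c in self.insertion_counts.values()):
            raise ValueError("insertion counts must be >= 0")
        self._leaves = _parse_topology(self.topology)

    # leaf roles -----------------------------------------------------------
    @property
    def leaves(self) -> tuple[str, str, str, str]:
        """(cherry_a, cherry_b, third, outgroup)."""
        return self._leaves

    @property
    def ingroup(self) -> tuple[str, str, str]:
        return self._leaves[:3]

    @property
    def outgroup(self) -> str:
        return self._leaves[3]

    def pattern_for_branch(self, branch: str) -> frozenset[str]:
        a, b, c, o = self._leaves
        if branch == INTERNAL_BRANCH:
            return frozenset((a, b))
        if branch in (a, b, c, o):
            return frozenset((branch,))
        raise ValueError(f"unknown branch {branch!r}")

    def internal_pattern_probs(self) -> dict[frozenset[str], float]:
        """Fixation probabilities of internal-branch events over leaf patterns."""
        a, b, c, _ = self._leaves
        p_conflict = (1.0 / 3.0) * float(np.exp(-self.tau))
        return {
            frozenset((a, b)): 1.0 - 2.0 * p_conflict,
            frozenset((a, c)): p_conflict,
            frozenset((b, c)): p_conflict,
        }

    def hybrid_pattern(self) -> frozenset[str]:
        a, b, c, _ = self._leaves
        return frozenset((a, c)) if self.hybrid_target == "conflict_13" else frozenset((b, c))


@dataclass
class InsertionEvent:
    """One simulated SINE insertion and its realized presence pattern."""

    event_id: str
    branch: str
    ancestral_position: int  # 0-based offset in ancestral coordinates; -1 = unplaced
    family: str
    tsd_length: int
    realized_pattern: frozenset[str]
    truncation_5p: int = 0
    truncation_3p: int = 0
    strand: str = "+"
    # filled by synthesize_genomes: species -> (contig, start, end, strand)
    coordinates: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)

    def __post_init__(self):
        if not 8 <= self.tsd_length <= 30:
            raise ValueError("tsd_length must lie in [8, 30]")
        if self.truncation_5p < 0 or self.truncation_3p < 0:
            raise ValueError("truncations must be >= 0")


@dataclass
class GenomeSet:
    """Named genome sequences plus the simulation truth table."""

    sequences: dict[str, str]
    truth: list[InsertionEvent]
    ancestral_length: int
    contig_name: str = "chr1"

    def truth_pattern_counts(
        self, tree: SpeciesTreeSpec, filter_passing_only: bool = False,
        max_truncation: int = 10,
    ) -> dict[str, int]:
        """Counts of events realizing each two-lineage hypothesis pattern.

        H1 = {cherry}, H2 = {cherry_a, third}, H3 = {cherry_b, third}. With
        ``filter_passing_only`` events truncated past ``max_truncation`` are
        excluded, mirroring the nearly-full-length locus filter.
        """
        a, b, c, _ = tree.leaves
        keys = {frozenset((a, b)): "H1", frozenset((a, c)): "H2", frozenset((b, c)): "H3"}
        out = {"H1": 0, "H2": 0, "H3": 0}
        for ev in self.truth:
            if filter_passing_only and (
                ev.truncation_5p >= max_truncation or ev.truncation_3p >= max_truncation
            ):
                continue
            lab = keys.get(ev.realized_pattern)
            if lab:
                out[lab] += 1
        return out


def default_element_library(seed: int = 7, families: tuple[str, ...] | None = None
                            ) -> dict[str, str]:
    """Deterministic synthetic SINE consensus library.

    Four tRNA-SINE-sized consensus sequences (150–220 nt) standing in for the
    WSINE1/WSINE1a/WALLSI1/WALLSI1a families of the marsupial repeat library.
    """
    if families is None:
        families = ("SINE1", "SINE1a", "SINE2", "SINE2a")
    lengths = (175, 190, 150, 220)
    rng = np.random.default_rng(seed)
    return {
        fam: "".join(rng.choice(BASES, size=lengths[i % len(lengths)]))
        for i, fam in enumerate(families)
    }


def simulate_marker_patterns(
    tree: SpeciesTreeSpec, n_events: int, seed: int
) -> list[InsertionEvent]:
    """Draw insertion events and their realized presence/absence patterns.

    Internal-branch events sort under the discordance closed form (see module
    docstring), then ``hybrid_fraction`` of them is rerouted to the tree's
    hybrid target pattern. Terminal-branch events mark only their own leaf.
    Positions are left unplaced (-1); :func:`synthesize_genomes` assigns them.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    branches = sorted(tree.insertion_counts)
    weights = np.array([tree.insertion_counts[b] for b in branches], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("insertion_counts must have positive total weight")
    weights /= weights.sum()
    families = sorted(default_element_library())
    probs = tree.internal_pattern_probs()
    patterns = list(probs)
    pvec = np.array([probs[p] for p in patterns])

    events: list[InsertionEvent] = []
    for i in range(n_events):
        branch = branches[rng.choice(len(branches), p=weights)]
        if branch == INTERNAL_BRANCH:
            if tree.hybrid_fraction > 0 and rng.random() < tree.hybrid_fraction:
                pattern = tree.hybrid_pattern()
            else:
                pattern = patterns[rng.choice(len(patterns), p=pvec)]
        else:
            pattern = tree.pattern_for_branch(branch)
        trunc5 = 0
        if tree.truncated_fraction > 0 and rng.random() < tree.truncated_fraction:
            trunc5 = int(rng.integers(11, 101))
        events.append(
            InsertionEvent(
                event_id=f"ev{i:05d}",
                branch=branch,
                ancestral_position=-1,
                family=families[int(rng.integers(len(families)))],
                tsd_length=int(rng.integers(8, 31)),
                realized_pattern=pattern,
                truncation_5p=trunc5,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return events


def _assign_positions(
    events: list[InsertionEvent], ancestral_length: int, rng: np.random.Generator,
    margin: int = 1500, min_spacing: int = 1200,
) -> None:
    """Place unpositioned events uniformly with a minimum pairwise spacing."""
    lo, hi = margin, ancestral_length - margin
    if hi - lo < (len(events) + 1) * min_spacing:
        raise ValueError("ancestral sequence too short for requested events")
    taken = sorted(
        ev.ancestral_position for ev in events if ev.ancestral_position >= 0
    )
    todo = [ev for ev in events if ev.ancestral_position < 0]
    placed: list[int] = list(taken)
    for ev in todo:
        for _ in range(10000):
            p = int(rng.integers(lo, hi))
            if all(abs(p - q) >= min_spacing for q in placed):
                placed.append(p)
                ev.ancestral_position = p
                break
        else:
            raise RuntimeError("could not place insertion with required spacing")


def _branch_mutations(
    length: int, rate: float, rng: np.random.Generator
) -> dict[int, str]:
    """Positions and replacement bases for one branch (uniform JC-like model)."""
    if rate <= 0:
        return {}
    n = rng.binomial(length, rate)
    pos = rng.choice(length, size=n, replace=False)
    return {int(p): BASES[int(rng.integers(4))] for p in pos}


def synthesize_genomes(
    events: list[InsertionEvent],
    tree: SpeciesTreeSpec,
    ancestral_length: int,
    element_library: dict[str, str],
    seed: int,
) -> GenomeSet:
    """Realize the simulated insertion history as nucleotide sequences.

    Each present insertion appears as (truncated) element flanked by an exact
    duplicated target site of ``tsd_length`` nt; substitutions are applied on
    the ancestral backbone per branch of the species tree. Truth coordinates
    of each element copy (excluding TSDs) are recorded per species, 0-based
    half-open.
    """
    if ancestral_length < 1000:
        raise ValueError("ancestral_length must be >= 1000")
    for ev in events:
        if ev.family not in element_library:
            raise KeyError(f"family {ev.family!r} missing from element library")
        if ev.ancestral_position >= ancestral_length:
            raise ValueError("event position exceeds ancestral length")
    rng = np.random.default_rng(seed)
    ancestral = "".join(rng.choice(BASES, size=ancestral_length))
    _assign_positions(events, ancestral_length, rng)

    a, b, c, o = tree.leaves
    rates = tree.branch_sub_rate
    mut_internal = _branch_mutations(ancestral_length, rates.get(INTERNAL_BRANCH, 0.0), rng)
    mut_term = {
        lf: _branch_mutations(ancestral_length, rates.get(lf, 0.0), rng)
        for lf in (a, b, c, o)
    }
    paths = {a: (mut_internal, mut_term[a]), b: (mut_internal, mut_term[b]),
             c: ({}, mut_term[c]), o: ({}, mut_term[o])}

    order = sorted(events, key=lambda e: e.ancestral_position)
    sequences: dict[str, str] = {}
    for sp in (a, b, c, o):
        anc = list(ancestral)
        for stage in paths[sp]:
            for p, base in stage.items():
                anc[p] = base
        anc_s = "".join(anc)
        parts: list[str] = []
        cursor = 0
        offset = 0
        for ev in order:
            if sp not in ev.realized_pattern:
                continue
            p, t = ev.ancestral_position, ev.tsd_length
            elem_full = element_library[ev.family]
            elem = elem_full[ev.truncation_5p : len(elem_full) - ev.truncation_3p]
            if ev.strand == "-":
                elem = revcomp(elem)
            tsd = anc_s[p : p + t]
            parts.append(anc_s[cursor:p])
            parts.append(tsd)
            start = offset + p + t
            ev.coordinates[sp] = ("chr1", start, start + len(elem), ev.strand)
            parts.append(elem)
            parts.append(tsd)
            cursor = p + t
            offset += len(elem) + t
        parts.append(anc_s[cursor:])
        sequences[sp] = "".join(parts)
    return GenomeSet(sequences=sequences, truth=events,
                     ancestral_length=ancestral_length)


def write_fixture(genomes: GenomeSet, out_dir, manifest: dict | None = None) -> dict:
    """Write one FASTA per species, a truth TSV and a run manifest.

    Deterministic: identical inputs give byte-identical files. Returns the
    paths written.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sp in sorted(genomes.sequences):
        fp = out / f"{sp}.fasta"
        rec = SeqRecord(Seq(genomes.sequences[sp]), id=genomes.contig_name,
                        description=sp)
        with open(fp, "w") as fh:
            SeqIO.write([rec], fh, "fasta")
        paths[sp] = str(fp)

    truth_fp = out / "truth.tsv"
    with open(truth_fp, "w") as fh:
        fh.write("event_id\tspecies\tcontig\tstart\tend\tstrand\tfamily\tpattern\n")
        for ev in sorted(genomes.truth, key=lambda e: e.event_id):
            pattern = ",".join(sorted(ev.realized_pattern))
            for sp in sorted(ev.coordinates):
                contig, s, e, strand = ev.coordinates[sp]
                fh.write(f"{ev.event_id}\t{sp}\t{contig}\t{s}\t{e}\t{strand}\t"
                         f"{ev.family}\t{pattern}\n")
    paths["truth"] = str(truth_fp)

    man = dict(manifest or {})
    man.setdefault("n_events", len(genomes.truth))
    man.setdefault("ancestral_length", genomes.ancestral_length)
    man["fasta_sha1"] = {
        sp: hashlib.sha1(genomes.sequences[sp].encode()).hexdigest()
        for sp in sorted(genomes.sequences)
    }
    man_fp = out / "manifest.yaml"
    with open(man_fp, "w") as fh:
        yaml.safe_dump(man, fh, sort_keys=True)
    paths["manifest"] = str(man_fp)
    return paths


def read_fixture_genomes(fasta_paths: dict[str, str]) -> dict[str, dict[str, str]]:
    """Read {species: fasta path} into {species: {contig: sequence}}."""
    out: dict[str, dict[str, str]] = {}
    for sp, fp in fasta_paths.items():
        out[sp] = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fp, "fasta")}
    return out
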