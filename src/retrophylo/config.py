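"""Pipeline-wide thresholds for locus selection, anchoring and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class PipelineConfig:
    """Thresholds applied across annotation, screening and marker validation.

    The headline criteria mirror the study design for diagnostic SINE loci:
    nearly full-length elements (truncations strictly under ``max_truncation``
    nt at either end), TE-sparse 500-nt flanks (under ``te_density_max``
    repeat coverage, per flank), element starts shifted across species by
    strictly less than ``shift_tolerance`` nt, target-site duplications of
    ``tsd_min``–``tsd_max`` nt, and presence/absence states consistent in at
    least ``min_lineage_representatives`` species per lineage.
    """

    max_truncation: int = 10          # nt, exclusive bound on 5'/3' truncation
    flank_len: int = 500              # nt of flank used for TE-density and anchoring
    te_density_max: float = 0.50      # max fraction of flank covered by repeats
    shift_tolerance: int = 3          # nt, exclusive bound on pairwise element shift
    tsd_min: int = 8                  # nt, shortest accepted target-site duplication
    tsd_max: int = 30                 # nt, longest accepted target-site duplication
    analysis_flank_len: int = 1000    # nt of flank per locus for sequence analyses
    min_lineage_representatives: int = 2

    # internal annotator / anchoring knobs
    scan_k: int = 12                  # seed length for consensus scanning
    scan_min_identity: float = 0.80   # min identity of a reported SINE copy
    anchor_k: int = 20                # seed length for flank anchoring
    anchor_min_identity: float = 0.90
    anchor_uniqueness_ratio: float = 1.2  # best/second-best anchor score ratio
    min_element_len: int = 40         # shortest inter-anchor gap callable present
    dup_min_identity: float = 0.90    # flank-duplication identity threshold
    dup_min_coverage: float = 0.80    # flank-duplication coverage threshold
    flank_transfer_max: int = 5       # nt of unexplained sequence at an empty site

    @property
    def empty_site_slack(self) -> int:
        """Largest inter-anchor gap still called a clean empty site.

        One retained target-site copy plus a few microindel nt.
        """
        return self.tsd_max + 5

    def to_dict(self) -> dict:
        return asdict(self)
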