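"""Screen-wide thresholds and enzymatic constants.

Every numeric cutoff used downstream lives here so that a single config
object fully determines a run: the >3-fold enrichment call, the 95%/90%
redundancy-clustering thresholds, the >15% AluI-site coverage filter, the
dual >=3-vectors-per-library suppressor criterion, the >1.66-fold expression
flags, the >500-AluI-site database filter, and the 1-mismatch allowance of
stem-loop-stem tag extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError

#: Standard pSUPER-family 9-nt hairpin loop.
DEFAULT_LOOP = "TTCAAGAGA"


@dataclass
class Config:
    """Thresholds and geometry shared by all pipeline stages.

    Attributes
    ----------
    fold_enrichment_min : float
        A vector is transforming iff post/pre normalized copy number is
        strictly greater than this (default 3).
    identity_min, coverage_min : float
        Redundancy clustering links two transcripts at >=95% identity and
        >=90% single-sided (shorter-sequence) coverage.
    alui_coverage_min : float
        A cluster survives iff its distinct transforming tags exceed this
        fraction of the representative's theoretical vector maximum.
    min_vectors_per_library : int
        Suppressor calls require at least this many distinct transforming
        vectors in each of the two libraries.
    expr_fold_threshold : float
        Strict threshold for the repressed/induced expression flags.
    max_alui_sites_db : int
        Reference transcripts with more AluI sites than this are dropped
        from the search database (strictly greater than).
    max_tag_mismatches : int
        Joint mismatch budget (loop match + stem complementarity) for
        accepting a stem-loop-stem read.
    loop_seq : str
        The 9-nt loop transcribed between the two stems.
    stem_len : int
        Guide length, 19 or 20 nt (20 = MmeI 18-bp capture + 2-nt overhang).
    knockdown_range : tuple of float
        Uniform range of per-vector knockdown efficacy for simulation.
    driver_excess : float
        Fold excess of driver over tester cDNA in the first hybridization.
    """

    fold_enrichment_min: float = 3.0
    identity_min: float = 0.95
    coverage_min: float = 0.90
    alui_coverage_min: float = 0.15
    min_vectors_per_library: int = 3
    expr_fold_threshold: float = 1.66
    max_alui_sites_db: int = 500
    max_tag_mismatches: int = 1
    max_map_mismatches: int = 0
    loop_seq: str = DEFAULT_LOOP
    loop_len: int = 9
    stem_len: int = 20
    knockdown_range: tuple[float, float] = (0.40, 0.80)
    driver_excess: float = 60.0
    pseudocount_cpm: float = 0.5
    merge_tags: bool = True
    merge_min_ratio: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "fold_enrichment_min": self.fold_enrichment_min,
            "identity_min": self.identity_min,
            "coverage_min": self.coverage_min,
            "alui_coverage_min": self.alui_coverage_min,
            "min_vectors_per_library": self.min_vectors_per_library,
            "expr_fold_threshold": self.expr_fold_threshold,
            "max_alui_sites_db": self.max_alui_sites_db,
            "driver_excess": self.driver_excess,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        if self.stem_len not in (19, 20):
            raise ConfigurationError(f"stem_len must be 19 or 20, got {self.stem_len}")
        if len(self.loop_seq) != self.loop_len:
            raise ConfigurationError(
                f"loop_seq length {len(self.loop_seq)} != loop_len {self.loop_len}"
            )
        lo, hi = self.knockdown_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(f"knockdown_range must lie inside (0, 1), got {self.knockdown_range}")
        if self.max_tag_mismatches < 0 or self.max_map_mismatches < 0:
            raise ConfigurationError("mismatch allowances must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["knockdown_range"] = list(self.knockdown_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        d = dict(d)
        if "knockdown_range" in d:
            d["knockdown_range"] = tuple(d["knockdown_range"])
        return cls(**d)
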