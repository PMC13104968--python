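"""Configuration objects for the simulator and the selection scan.

Dates are stored in years before present (BP, positive = older).  Analysis
time is ``t = -date_bp / 1000`` (units of 1,000 years, kyr), so a positive
regression slope always means "rising toward the present".
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Ancestry-proportion schedule emulating the three-way Holocene turnover in
# West Eurasia: hunter-gatherers, then incoming farmers, then steppe-related
# ancestry.  Intervals are (start_bp, end_bp] with start_bp > end_bp.
DEFAULT_ADMIXTURE_SCHEDULE: tuple[tuple[float, float, tuple[float, ...]], ...] = (
    (10_000.0, 8_000.0, (1.00, 0.00, 0.00)),
    (8_000.0, 5_000.0, (0.20, 0.80, 0.00)),
    (5_000.0, 0.0, (0.15, 0.45, 0.40)),
)


@dataclass
class SimConfig:
    """Parameters of the forward simulator and cohort sampler.

    The defaults describe a compact Holocene-like design: ~10,000 years of
    Wright-Fisher evolution (400 generations at 25 years/generation) in a
    diploid population of effective size 10,000, with three ancestral
    components whose mixture proportions shift over time (the confounding
    the scan's covariates must absorb), block-structured LD, and aDNA-style
    missingness plus pseudo-haploid calls.
    """

    seed: int = 0
    n_individuals: int = 800
    n_blocks: int = 40
    variants_per_block: int = 50
    generations: int = 400
    pop_size: int = 10_000
    frac_selected: float = 0.05
    s_range: tuple[float, float] = (0.005, 0.03)
    n_ancestries: int = 3
    admixture_schedule: tuple[tuple[float, float, tuple[float, ...]], ...] = (
        DEFAULT_ADMIXTURE_SCHEDULE
    )
    missing_rate: float = 0.05
    pseudohaploid_rate: float = 0.30
    years_per_generation: float = 25.0
    fst: float = 0.10          # Balding-Nichols divergence of ancestral freqs
    # per-block exchangeable genotype correlation is drawn uniformly from this
    # range, giving the spread in LD scores the regression needs
    ld_r_range: tuple[float, float] = (0.1, 0.9)
    ancestry_concentration: float = 50.0  # Dirichlet conc. of individual ancestry

    def __post_init__(self) -> None:
        if self.n_ancestries == 1:
            # single-component runs ignore the three-way default schedule
            span = self.generations * self.years_per_generation
            self.admixture_schedule = ((span, 0.0, (1.0,)),)
        for p, name in [
            (self.frac_selected, "frac_selected"),
            (self.missing_rate, "missing_rate"),
            (self.pseudohaploid_rate, "pseudohaploid_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.s_range
        if not (-0.5 < lo <= hi < 0.5):
            raise ValueError(f"s_range must lie within (-0.5, 0.5), got {self.s_range}")
        lo_r, hi_r = self.ld_r_range
        if not 0.0 <= lo_r <= hi_r < 1.0:
            raise ValueError("ld_r_range must lie within [0, 1)")
        for start, end, props in self.admixture_schedule:
            if len(props) != self.n_ancestries:
                raise ValueError("admixture proportions must have n_ancestries entries")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("ancestry proportions must sum to 1 per interval")
            if start <= end:
                raise ValueError("schedule intervals must run old (start) to young (end)")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.variants_per_block

    @property
    def time_span_years(self) -> float:
        return self.generations * self.years_per_generation


@dataclass
class ScanConfig:
    """Options of the per-variant selection scan.

    ``genomic_control`` rescales all standard errors by sqrt(lambda_GC)
    with lambda_GC = median(Z^2)/0.4549; this is the scan's calibration
    step against residual drift/structure variance that the fixed-effect
    regression does not model.
    """

    n_covariates: int | None = None    # ancestry columns used; None = all
    maf_min: float = 0.01
    min_n: int = 30
    genomic_control: bool = True
    pseudohaploid_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.min_n < 3:
            raise ValueError("min_n must be >= 3")
        if not 0.0 < self.pseudohaploid_weight <= 1.0:
            raise ValueError("pseudohaploid_weight must be in (0, 1]")
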