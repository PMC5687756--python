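"""Survey layout and variance-component containers.

The survey layout is hierarchical: sites contain transects, each transect is
divided into contiguous sections (the observation unit), each section's video
is scored by several observers, and each observer reads it several times.
The reference layout used throughout the package is the validation study's:
3 sites with 5, 3 and 5 transects; five 4 m x 0.8 m (3.2 m^2) sections per
20 m transect; 2 observers; 2 readings per observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "SurveyDesign",
    "VarianceComponents",
    "GeneratorConfig",
    "PrecisionQuery",
    "reference_design",
    "reference_variance_components",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Structural constants of a nested towed-video survey.

    Attributes
    ----------
    n_sites : int
        Number of sites (fixed factor levels).
    transects_per_site : tuple of int
        Transects surveyed at each site; may be unequal.
    sections_per_transect : int
        Sections per transect (``b`` in the precision formula).
    observers : int
        Independent video observers (``c``).
    readings_per_observer : int
        Replicate readings of each section by each observer (``n``).
    section_length, section_width : float
        Section geometry in metres.
    """

    n_sites: int = 3
    transects_per_site: tuple[int, ...] = (5, 3, 5)
    sections_per_transect: int = 5
    observers: int = 2
    readings_per_observer: int = 2
    section_length: float = 4.0
    section_width: float = 0.8

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.sections_per_transect < 1:
            raise ValueError("site and section counts must be >= 1")
        if self.observers < 1 or self.readings_per_observer < 1:
            raise ValueError("observer and reading counts must be >= 1")
        if len(self.transects_per_site) != self.n_sites:
            raise ValueError(
                f"transects_per_site has length {len(self.transects_per_site)}, "
                f"expected n_sites={self.n_sites}"
            )
        if any(t < 1 for t in self.transects_per_site):
            raise ValueError("every site needs at least one transect")
        if self.section_length <= 0 or self.section_width <= 0:
            raise ValueError("section geometry must be positive")

    @property
    def section_area(self) -> float:
        """Area of one section in square metres."""
        return self.section_length * self.section_width

    @property
    def n_transects(self) -> int:
        return sum(self.transects_per_site)

    @property
    def n_sections(self) -> int:
        return self.n_transects * self.sections_per_transect

    @property
    def n_readings(self) -> int:
        """Total reading records the design produces."""
        return self.n_sections * self.observers * self.readings_per_observer

    @property
    def is_balanced(self) -> bool:
        """True when every site has the same number of transects."""
        return len(set(self.transects_per_site)) == 1


@dataclass(frozen=True)
class VarianceComponents:
    """The seven random-effect variances of the mixed model.

    Units are (oysters per section)^2 throughout. ``s_ob2`` is the observer
    main effect, ``s_tr2`` transects within sites, ``s_se2`` sections within
    transects, the three interaction components follow, and ``s_e2`` is the
    residual: variability between replicate readings by the same observer.
    """

    s_ob2: float = 0.0
    s_tr2: float = 0.0
    s_se2: float = 0.0
    s_obsi2: float = 0.0
    s_trob2: float = 0.0
    s_seob2: float = 0.0
    s_e2: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @property
    def total(self) -> float:
        """Sum of all seven components."""
        return sum(self.as_dict().values())

    def shares(self) -> dict[str, float]:
        """Each component's fraction of total random variability."""
        tot = self.total
        if tot <= 0:
            raise ValueError("shares undefined: total random variability is zero")
        return {k: v / tot for k, v in self.as_dict().items()}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    Two modes:

    ``"gaussian-vc"``
        Reading-level values are sums of Gaussian random effects — the exact
        data-generating process of the mixed linear model the ANOVA and REML
        estimators assume. Values need not be integers.
    ``"mechanistic"``
        Integer oysters are placed in sections from a latent hierarchical
        mean, then observed imperfectly: each oyster is detected per reading
        with a status-conditional probability and, if detected, may be
        assigned the wrong status.
    """

    mode: str = "gaussian-vc"
    grand_mean: float = 10.0
    site_effects: tuple[float, ...] = (0.0, 0.0, 0.0)
    vc: VarianceComponents = field(default_factory=VarianceComponents)
    dead_grand_mean: float = 10.0
    dead_site_effects: tuple[float, ...] | None = None
    dead_vc: VarianceComponents | None = None
    p_detect_living: float = 0.8
    p_detect_dead: float = 0.5
    p_live_classified_dead: float = 0.0
    p_dead_classified_living: float = 0.0
    p_probably_given_detected_living: float = 0.5
    p_in_cluster: float = 0.0
    p_covered: float = 0.0
    covered_detect_multiplier: float = 1.0
    count_model: str = "round"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian-vc", "mechanistic"):
            raise ValueError(f"unknown generator mode {self.mode!r}")
        if self.count_model not in ("round", "poisson"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        for name in (
            "p_detect_living",
            "p_detect_dead",
            "p_live_classified_dead",
            "p_dead_classified_living",
            "p_probably_given_detected_living",
            "p_in_cluster",
            "p_covered",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class PrecisionQuery:
    """Design knobs of the precision formula: a transects, b sections per
    transect, c observers, n readings per observer."""

    a: int
    b: int
    c: int = 1
    n: int = 1

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "n"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")


def reference_design() -> SurveyDesign:
    """The validation study's layout: (3 sites; 5,3,5 transects; 5 sections;
    2 observers; 2 readings; 4 m x 0.8 m sections)."""
    return SurveyDesign()


def reference_variance_components() -> VarianceComponents:
    """REML variance components estimated in the validation study
    (units: (oysters per 3.2 m^2 section)^2)."""
    return VarianceComponents(
        s_ob2=0.1,
        s_tr2=1.1,
        s_se2=26.2,
        s_obsi2=0.0,
        s_trob2=0.1,
        s_seob2=0.0,
        s_e2=1.6,
    )


def reference_generator_config(mode: str = "mechanistic", seed: int = 0) -> GeneratorConfig:
    """Generator preset emulating the validation study.

    Detection probabilities reproduce the study's recovery anchors: the
    "probably living" category alone recovers about 40% of living oysters
    (0.8 detection x 0.5 "probably" split), merged living lands in the
    70-80% band, and about half of the dead are found. Misclassification
    probabilities match the confusion-matrix off-diagonal rates (25/137,
    26/133). Spatial variance components and the per-section mean (~4
    living oysters per 3.2 m^2) match the study's estimates.
    """
    return GeneratorConfig(
        mode=mode,
        grand_mean=4.0,
        site_effects=(0.0, 0.0, 0.0),
        vc=VarianceComponents(s_tr2=1.1, s_se2=26.2),
        dead_grand_mean=3.7,
        p_detect_living=0.8,
        p_detect_dead=0.5,
        p_live_classified_dead=0.18,
        p_dead_classified_living=0.20,
        p_probably_given_detected_living=0.5,
        seed=seed,
    )


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different root seed."""
    return replace(config, seed=seed)
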