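"""Synthetic tractometry cohorts with known ground truth.

No imaging data ships with this package, so every stage of the pipeline
is exercised on simulated cohorts that reproduce the statistical
structure the analysis assumes: per-tract Gaussian FA and RD in healthy
controls (FA truncated to [0, 1], RD to (0, inf)), sex-stratified
control groups of 50, and patient phenotypes defined by *signatures* —
tract sets in which FA is depressed and RD elevated by a known effect
size delta, expressed in control-SD units.  Because the downstream
inference is rank-based, the exact generative family is immaterial to
calibration; a log-normal RD option and an equicorrelation stress
parameter are provided to probe distribution-robustness.

Per-tract population means and SDs are drawn once from literature-
plausible ranges using the top-level seed, so controls and patients of
one study share the same tract-level population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import CohortTable, Role, Sex, SubjectRecord, TractMetrics
from .registry import Hemisphere, TractRegistry, default_tract_registry

__all__ = [
    "SimulationParams",
    "PhenotypeSignature",
    "simulate_controls",
    "simulate_patient",
    "simulate_study",
    "builtin_signatures",
    "left_dominant_signature",
    "DEFAULT_GROUP_SIZES",
]


@dataclass
class SimulationParams:
    """Generative settings for a synthetic study.

    Ranges are (low, high) bounds from which each tract's population
    mean/SD is drawn uniformly, once, from ``seed``.  ``effect_size`` is
    the patient shift delta in units of the tract's control SD (FA
    shifted down, RD up).  RD is in mm^2/s.
    """

    seed: int
    registry: TractRegistry = field(default_factory=default_tract_registry)
    n_controls_per_sex: int = 50
    fa_mean_range: tuple[float, float] = (0.30, 0.65)
    fa_sd_range: tuple[float, float] = (0.02, 0.05)
    rd_mean_range: tuple[float, float] = (5.0e-4, 9.0e-4)
    rd_sd_range: tuple[float, float] = (2.0e-5, 6.0e-5)
    effect_size: float = 3.0
    missing_prob: float = 0.0
    age_mean: float = 59.0
    age_sd: float = 9.8
    age_bounds: tuple[float, float] = (35.0, 85.0)
    rd_family: str = "normal"  # "normal" | "lognormal"
    equicorrelation: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for lo, hi in (self.fa_mean_range, self.fa_sd_range,
                       self.rd_mean_range, self.rd_sd_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must lie in [0, 1)")
        if not 0.0 <= self.equicorrelation < 1.0:
            raise ValueError("equicorrelation must lie in [0, 1)")
        if self.rd_family not in ("normal", "lognormal"):
            raise ValueError(f"unknown rd_family {self.rd_family!r}")


@dataclass(frozen=True)
class PhenotypeSignature:
    """A phenotype's affected-tract set.

    ``tracts`` is the union signature used by default for both metrics;
    ``fa_tracts``/``rd_tracts`` optionally restrict the shift per
    metric.  ``multipliers`` scales delta per tract.
    """

    label: str
    tracts: tuple[str, ...]
    fa_tracts: tuple[str, ...] | None = None
    rd_tracts: tuple[str, ...] | None = None
    multipliers: Mapping[str, float] | None = None

    def delta_for(self, tract: str, delta: float) -> float:
        if self.multipliers and tract in self.multipliers:
            return delta * self.multipliers[tract]
        return delta

    def shifted(self, metric: str) -> tuple[str, ...]:
        per_metric = self.fa_tracts if metric == "fa" else self.rd_tracts
        return per_metric if per_metric is not None else self.tracts


# ---------------------------------------------------------------------------
# population parameters and low-level sampling


@dataclass(frozen=True)
class _TractPopulation:
    names: tuple[str, ...]
    fa_mu: np.ndarray
    fa_sd: np.ndarray
    rd_mu: np.ndarray
    rd_sd: np.ndarray


def _tract_population(params: SimulationParams) -> _TractPopulation:
    """Per-tract population parameters; deterministic in ``params.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0]))
    n = len(params.registry)
    return _TractPopulation(
        names=tuple(params.registry.names),
        fa_mu=rng.uniform(*params.fa_mean_range, size=n),
        fa_sd=rng.uniform(*params.fa_sd_range, size=n),
        rd_mu=rng.uniform(*params.rd_mean_range, size=n),
        rd_sd=rng.uniform(*params.rd_sd_range, size=n),
    )


def _truncate(rng: np.random.Generator, x: np.ndarray, mu: np.ndarray,
              sd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Redraw out-of-bounds values (truncated-normal by rejection)."""
    bad = (x <= lo) | (x >= hi)
    while np.any(bad):
        x = np.where(bad, rng.normal(mu, sd), x)
        bad = (x <= lo) | (x >= hi)
    return x


def _correlated_normals(rng: np.random.Generator, n: int,
                        rho: float) -> np.ndarray:
    if rho == 0.0:
        return rng.standard_normal(n)
    shared = rng.standard_normal()
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(n)


def _draw_profile(rng: np.random.Generator, pop: _TractPopulation,
                  params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """One control-like (fa, rd) vector over all tracts."""
    z_fa = _correlated_normals(rng, len(pop.names), params.equicorrelation)
    fa = pop.fa_mu + pop.fa_sd * z_fa
    fa = _truncate(rng, fa, pop.fa_mu, pop.fa_sd, 0.0, 1.0)
    z_rd = _correlated_normals(rng, len(pop.names), params.equicorrelation)
    if params.rd_family == "lognormal":
        # match the target mean/SD via log-normal moment inversion
        s2 = np.log1p((pop.rd_sd / pop.rd_mu) ** 2)
        mu_log = np.log(pop.rd_mu) - 0.5 * s2
        rd = np.exp(mu_log + np.sqrt(s2) * z_rd)
    else:
        rd = pop.rd_mu + pop.rd_sd * z_rd
        rd = _truncate(rng, rd, pop.rd_mu, pop.rd_sd, 0.0, np.inf)
    return fa, rd


def _draw_age(rng: np.random.Generator, params: SimulationParams) -> float:
    lo, hi = params.age_bounds
    age = rng.normal(params.age_mean, params.age_sd)
    while not lo <= age <= hi:
        age = rng.normal(params.age_mean, params.age_sd)
    return float(age)


def _metrics_from_arrays(rng: np.random.Generator, pop: _TractPopulation,
                         fa: np.ndarray, rd: np.ndarray,
                         missing_prob: float) -> TractMetrics:
    values: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(pop.names):
        if missing_prob > 0.0 and rng.random() < missing_prob:
            continue
        values[name] = (float(fa[i]), float(rd[i]))
    return TractMetrics(values)


# ---------------------------------------------------------------------------
# public generators


def simulate_controls(params: SimulationParams) -> CohortTable:
    """Simulate the normative cohort: ``n_controls_per_sex`` per sex."""
    pop = _tract_population(params)
    cohort = CohortTable()
    for sex_idx, sex in enumerate((Sex.MALE, Sex.FEMALE)):
        for i in range(params.n_controls_per_sex):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(params.seed), 1, sex_idx, i]))
            fa, rd = _draw_profile(rng, pop, params)
            cohort.add(SubjectRecord(
                subject_id=f"HC-{sex.value[0].upper()}-{i + 1:03d}",
                sex=sex, age=_draw_age(rng, params), role=Role.CONTROL,
                metrics=_metrics_from_arrays(rng, pop, fa, rd,
                                             params.missing_prob),
            ))
    return cohort


def simulate_patient(signature: PhenotypeSignature, params: SimulationParams,
                     subject_seed: int, *, sex: Sex | str = Sex.MALE,
                     subject_id: str | None = None) -> SubjectRecord:
    """Simulate one patient: control-like profile shifted in signature tracts.

    FA is lowered by delta * sigma_t and RD raised by delta * tau_t in
    the signature tracts (per-tract multipliers applied), then
    re-truncated to the physical ranges.
    """
    sex = Sex(sex)
    registry = params.registry
    for tract in signature.tracts:
        registry.lookup(tract)  # raises UnknownTractError if absent

    pop = _tract_population(params)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 2, int(subject_seed)]))
    fa, rd = _draw_profile(rng, pop, params)

    index = {name: i for i, name in enumerate(pop.names)}
    for tract in signature.shifted("fa"):
        i = index[registry.resolve(tract)]
        fa[i] -= signature.delta_for(tract, params.effect_size) * pop.fa_sd[i]
    for tract in signature.shifted("rd"):
        i = index[registry.resolve(tract)]
        rd[i] += signature.delta_for(tract, params.effect_size) * pop.rd_sd[i]
    fa = np.clip(fa, 1e-9, 1.0)
    rd = np.maximum(rd, 1e-12)

    return SubjectRecord(
        subject_id=subject_id or f"{signature.label}-{subject_seed:04d}",
        sex=sex, age=_draw_age(rng, params), role=Role.PATIENT,
        phenotype=signature.label,
        metrics=_metrics_from_arrays(rng, pop, fa, rd, params.missing_prob),
    )


# (n_male, n_female) per phenotype, defaults of the 160-subject design
DEFAULT_GROUP_SIZES: dict[str, tuple[int, int]] = {
    "bvFTD": (4, 3),
    "nfvPPA": (5, 4),
    "svPPA": (2, 1),
    "ALSFTD-C9+": (13, 8),
    "ALSFTD-C9NEG": (13, 7),
}


def simulate_study(params: SimulationParams,
                   group_sizes: Mapping[str, tuple[int, int]] | None = None,
                   signatures: Mapping[str, PhenotypeSignature] | None = None,
                   ) -> tuple[CohortTable, CohortTable]:
    """Simulate a full two-cohort study: (controls, patients).

    Defaults to 50 controls per sex and the five phenotype groups at
    sizes (7, 9, 3, 21, 20) with the published sex splits.
    """
    signatures = dict(signatures) if signatures is not None else builtin_signatures(params.registry)
    group_sizes = dict(group_sizes) if group_sizes is not None else dict(DEFAULT_GROUP_SIZES)

    controls = simulate_controls(params)
    patients = CohortTable()
    subject_seed = 0
    for label, (n_male, n_female) in group_sizes.items():
        signature = signatures[label]
        for sex, count in ((Sex.MALE, n_male), (Sex.FEMALE, n_female)):
            for i in range(count):
                subject_seed += 1
                patients.add(simulate_patient(
                    signature, params, subject_seed, sex=sex,
                    subject_id=f"{label}-{sex.value[0].upper()}-{i + 1:02d}",
                ))
    return controls, patients


# ---------------------------------------------------------------------------
# built-in phenotype signatures

_BVFTD_FA = ("Corpus callosum: genu",)
_BVFTD_RD = (
    "Arcuate fascicle left",
    "Corpus callosum: rostrum",
    "Corpus callosum: genu",
    "Corticospinal tract right",
    "Fronto-pontine tract right",
    "Inferior occipito-frontal fascicle right",
    "Superior thalamic radiation left",
    "Superior thalamic radiation right",
    "Uncinate fascicle right",
    "Thalamo-premotor right",
    "Striato-fronto-orbital left",
    "Striato-fronto-orbital right",
    "Striato-premotor right",
)

_NFVPPA_FA = (
    "Corpus callosum: genu",
    "Cingulum left",
    "Superior longitudinal fascicle I left",
    "Superior longitudinal fascicle II left",
    "Thalamo-premotor left",
)
_NFVPPA_RD = (
    "Arcuate fascicle left",
    "Arcuate fascicle right",
    "Anterior thalamic radiation left",
    "Anterior thalamic radiation right",
    "Corpus callosum: rostrum",
    "Corpus callosum: genu",
    "Corpus callosum: rostral body",
    "Corpus callosum: posterior midbody",
    "Cingulum left",
    "Cingulum right",
    "Fronto-pontine tract left",
    "Fronto-pontine tract right",
    "Inferior occipito-frontal fascicle left",
    "Inferior occipito-frontal fascicle right",
    "Inferior longitudinal fascicle right",
    "Optic radiation left",
    "Optic radiation right",
    "Superior longitudinal fascicle I left",
    "Superior longitudinal fascicle I right",
    "Superior longitudinal fascicle II left",
    "Superior longitudinal fascicle II right",
    "Superior longitudinal fascicle III left",
    "Superior longitudinal fascicle III right",
    "Uncinate fascicle left",
    "Thalamo-premotor left",
    "Thalamo-parietal left",
    "Thalamo-parietal right",
    "Thalamo-occipital left",
    "Thalamo-occipital right",
    "Striato-fronto-orbital left",
    "Striato-fronto-orbital right",
)

_SVPPA_FA = (
    "Inferior occipito-frontal fascicle left",
    "Superior longitudinal fascicle III left",
)
_SVPPA_RD = (
    "Arcuate fascicle left",
    "Arcuate fascicle right",
    "Corpus callosum: rostrum",
    "Corpus callosum: genu",
    "Corpus callosum: isthmus",
    "Cingulum left",
    "Inferior occipito-frontal fascicle left",
    "Inferior occipito-frontal fascicle right",
    "Inferior longitudinal fascicle left",
    "Inferior longitudinal fascicle right",
    "Optic radiation left",
    "Optic radiation right",
    "Superior longitudinal fascicle I left",
    "Superior longitudinal fascicle I right",
    "Superior longitudinal fascicle II left",
    "Superior longitudinal fascicle II right",
    "Superior longitudinal fascicle III left",
    "Superior thalamic radiation right",
    "Uncinate fascicle left",
    "Thalamo-parietal left",
    "Thalamo-parietal right",
    "Thalamo-occipital left",
    "Thalamo-occipital right",
    "Striato-fronto-orbital left",
    "Striato-fronto-orbital right",
)

_C9POS_FA = (
    "Arcuate fascicle right",
    "Corpus callosum: rostrum",
    "Corpus callosum: genu",
    "Corpus callosum: anterior midbody",
    "Corpus callosum: posterior midbody",
    "Corpus callosum: isthmus",
    "Corpus callosum: splenium",
    "Cingulum left",
    "Cingulum right",
    "Corticospinal tract left",
    "Corticospinal tract right",
    "Fronto-pontine tract right",
    "Optic radiation left",
    "Parieto-occipital pontine right",
    "Superior longitudinal fascicle I left",
    "Superior longitudinal fascicle I right",
    "Superior longitudinal fascicle II left",
    "Superior longitudinal fascicle II right",
    "Superior longitudinal fascicle III right",
    "Superior thalamic radiation right",
    "Thalamo-occipital left",
    "Striato-fronto-orbital right",
)
_C9POS_RD = (
    "Arcuate fascicle left",
    "Arcuate fascicle right",
    "Corpus callosum: rostrum",
    "Corpus callosum: genu",
    "Corpus callosum: rostral body",
    "Corpus callosum: anterior midbody",
    "Corpus callosum: posterior midbody",
    "Corpus callosum: isthmus",
    "Corpus callosum: splenium",
    "Cingulum left",
    "Cingulum right",
    "Corticospinal tract left",
    "Corticospinal tract right",
    "Fronto-pontine tract left",
    "Fronto-pontine tract right",
    "Inferior cerebellar peduncle left",
    "Inferior cerebellar peduncle right",
    "Inferior occipito-frontal fascicle left",
    "Inferior occipito-frontal fascicle right",
    "Inferior longitudinal fascicle left",
    "Inferior longitudinal fascicle right",
    "Optic radiation left",
    "Optic radiation right",
    "Parieto-occipital pontine left",
    "Parieto-occipital pontine right",
    "Superior cerebellar peduncle right",
    "Superior longitudinal fascicle I left",
    "Superior longitudinal fascicle I right",
    "Superior longitudinal fascicle II left",
    "Superior longitudinal fascicle II right",
    "Superior longitudinal fascicle III left",
    "Superior longitudinal fascicle III right",
    "Superior thalamic radiation left",
    "Superior thalamic radiation right",
    "Uncinate fascicle left",
    "Uncinate fascicle right",
    "Thalamo-parietal right",
    "Thalamo-occipital left",
    "Thalamo-occipital right",
    "Striato-fronto-orbital right",
)

# Synthetic reconstruction: the C9orf72-negative ALS-FTD tract list is not
# available as a printed table in our sources; this bilateral, symmetric set
# (corticospinal tracts, corpus callosum, cerebellar peduncles, arcuate,
# uncinate, cingulum and the long association fascicles) follows the
# qualitative description of that phenotype's white-matter involvement.
_C9NEG = tuple(
    f"{base} {side}"
    for base in (
        "Corticospinal tract",
        "Inferior cerebellar peduncle",
        "Superior cerebellar peduncle",
        "Arcuate fascicle",
        "Uncinate fascicle",
        "Cingulum",
        "Inferior longitudinal fascicle",
        "Inferior occipito-frontal fascicle",
        "Superior longitudinal fascicle I",
        "Superior longitudinal fascicle II",
        "Superior longitudinal fascicle III",
    )
    for side in ("left", "right")
) + tuple(f"Corpus callosum: {seg}" for seg in (
    "rostrum", "genu", "rostral body", "anterior midbody",
    "posterior midbody", "isthmus", "splenium"))


def _union(*groups: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for grp in groups:
        for name in grp:
            seen.setdefault(name, None)
    return tuple(seen)


def builtin_signatures(registry: TractRegistry | None = None,
                       ) -> dict[str, PhenotypeSignature]:
    """The five built-in phenotype signatures.

    Each signature's tract set is the union of that phenotype's
    significant FA and RD tracts (per-metric subsets retained on the
    signature object).  The ALSFTD-C9NEG set is a synthetic
    reconstruction (see module comment above its definition).  All
    names are validated against the registry.
    """
    registry = registry or default_tract_registry()
    specs = {
        "bvFTD": (_BVFTD_FA, _BVFTD_RD),
        "nfvPPA": (_NFVPPA_FA, _NFVPPA_RD),
        "svPPA": (_SVPPA_FA, _SVPPA_RD),
        "ALSFTD-C9+": (_C9POS_FA, _C9POS_RD),
        "ALSFTD-C9NEG": (_C9NEG, _C9NEG),
    }
    out: dict[str, PhenotypeSignature] = {}
    for label, (fa, rd) in specs.items():
        union = _union(fa, rd)
        for name in union:
            registry.lookup(name)
        out[label] = PhenotypeSignature(label=label, tracts=union,
                                        fa_tracts=tuple(fa),
                                        rd_tracts=tuple(rd))
    return out


def left_dominant_signature(registry: TractRegistry | None = None,
                            ) -> PhenotypeSignature:
    """Strongly left-lateralised signature for laterality experiments.

    The left-hemisphere members of the nfvPPA union signature — the
    language-network pattern with its right-hemisphere counterparts
    removed, so the expected asymmetry of affected-tract counts is
    unambiguous.
    """
    registry = registry or default_tract_registry()
    base = builtin_signatures(registry)["nfvPPA"]
    left = tuple(t for t in base.tracts
                 if registry.lookup(t).hemisphere is Hemisphere.LEFT)
    return PhenotypeSignature(label="left-dominant", tracts=left)
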