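"""Study-shaped synthetic data with known ground truth.

The generator emulates the structure of a two-treatment (control vs
heat, n = 6 biological replicates) culture experiment profiled on three
chemical layers: ~17 elements, ~120 metabolites and ~163 volatiles,
with 5 medium-only water blanks and technical duplicates for the
volatile sampling.

Abundance model, per analyte a and biological sample s (log scale):

    log x_as = mu_a + beta_a * 1[s in heat] + lambda_a f_{k(a),s} + eps_as

with one standard-normal latent factor f_k per planted correlation
cluster and loadings of common sign, so recovered clusters are
positively correlated.  The total within-group variance is held at
sigma^2 for every analyte: cluster members split it between the shared
factor and the independent residual, lambda_a^2 = cluster_loading *
sigma^2 and Var(eps) = (1 - cluster_loading) * sigma^2, so planting a
cluster raises co-variation without inflating (or deflating) the
replicate noise any single analyte shows.  ``cluster_loading`` is thus
the fraction of replicate variability shared within a module, and
equals the within-cluster residual correlation.  Exponentiation keeps
raw abundances positive (log-normal peak areas / concentrations).

Each layer's observed values embed the *inverse* of its normalisation
ladder — element concentrations are per-cell signal x total cells /
dry mass, peak areas are per-cell signal x cells x (IS area / nominal)
— so that running the ladder recovers the per-cell biology exactly.

Volatiles additionally pass a detection model: measurements in an
analyte's low-abundance half drop out with a configurable probability;
unique-to-treatment analytes are structural absences (detection forced
off in the other group, never low abundance); contaminant analytes are
present in the blanks (and at the same level in every sample) and half
of them carry recognisable artefact names for the exclusion list.

Carbon, nitrogen and phosphorus are planted with the study's
stoichiometry: control C:N:P of 14:3:1 (molar, P = 1) shifting to
24:6:1 under heat, with a tighter residual spread than free analytes
(elemental fractions are physiologically regulated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnalyteTable,
    CONTROL,
    HEAT,
    SampleMeta,
    StepRecord,
    ValidationError,
)
from .normalize import ATOMIC_MASS

_ELEMENT_POOL = [
    "C", "N", "P", "K", "Ca", "Mg", "Na", "S", "Sr", "Fe", "Zn",
    "Mn", "Cu", "Mo", "Ni", "Co", "Se", "B", "Ba", "Al", "V", "Cr",
]

_VOC_CLASSES = [
    "alkane", "alkene", "aromatic", "aldehyde", "ketone", "ester",
    "alcohol", "furan", "halogenated", "sulfur", "terpene",
]

_IS_NOMINAL = 1.0e5  # nominal internal-standard peak area

# molar ratios relative to P=1: control 14:3:1 -> heat 24:6:1
_CNP_CONTROL = {"C": 14.0, "N": 3.0, "P": 1.0}
_CNP_HEAT = {"C": 24.0, "N": 6.0, "P": 1.0}
_SIGMA_STOICH = 0.15  # tighter spread for regulated elemental fractions


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the emulated study design."""

    n_per_group: int = 6
    n_elements: int = 17
    n_metabolites: int = 120
    n_volatiles: int = 163
    n_blanks: int = 5
    n_technical_reps: int = 2
    effect_fraction: float = 0.18
    effect_size: float = 2.0
    sigma: float = 0.5
    cluster_spec: tuple[int, ...] = (23, 5, 3, 2, 2)
    cluster_loading: float = 0.9
    detection_dropout: float = 0.1
    n_unique_heat: int = 66
    n_unique_control: int = 11
    contaminant_fraction: float = 0.1
    cv_technical: float = 0.1
    cv_internal_standard: float = 0.05
    plant_stoichiometry: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("effect_fraction", "detection_dropout", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.cluster_loading < 1.0:
            raise ValidationError(
                "cluster_loading is a variance fraction and must lie in [0, 1)"
            )
        for name in ("n_per_group", "n_elements", "n_metabolites", "n_volatiles",
                     "n_blanks", "n_technical_reps"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if any(c < 2 for c in self.cluster_spec):
            raise ValidationError("cluster sizes must be >= 2")
        if self.n_unique_heat + self.n_unique_control > self.n_volatiles:
            raise ValidationError("unique-to-treatment sets exceed n_volatiles")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator (oracle for recovery tests)."""

    differential: dict[str, float]  # prefixed id -> signed log-shift beta
    cluster_membership: dict[str, int]  # prefixed id -> cluster index
    contaminant_ids: set[str]  # volatile-layer ids
    known_artefact_ids: set[str]  # subset with recognisable names
    unique_to_heat_ids: set[str]  # volatile-layer ids
    unique_to_control_ids: set[str]
    analyte_universe: set[str] = field(default_factory=set)  # prefixed ids

    @property
    def differential_ids(self) -> set[str]:
        return set(self.differential)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    samples: list[SampleMeta]  # 2 x n_per_group biological samples
    elements: AnalyteTable
    metabolites: AnalyteTable
    volatiles: AnalyteTable  # with technical duplicates
    blanks: AnalyteTable
    metabolite_is: pd.Series
    volatile_is: pd.Series
    blank_is: pd.Series
    known_artefacts: list[str]
    truth: SyntheticTruth


def _element_names(n: int) -> list[str]:
    if n <= len(_ELEMENT_POOL):
        return _ELEMENT_POOL[:n]
    return _ELEMENT_POOL + [f"El{i:02d}" for i in range(n - len(_ELEMENT_POOL))]


def _stoich_percell_mu() -> dict[str, float]:
    """Baseline per-cell log means giving the control C:N:P molar ratio.

    Anchored at ~30% carbon by dry mass for a 0.01 g pellet of 7.5e6
    cells (4e-4 ug C per cell)."""
    c_percell = 4.0e-4  # ug per cell
    out = {"C": math.log(c_percell)}
    for el in ("N", "P"):
        mass_ratio = (_CNP_CONTROL[el] * ATOMIC_MASS[el]) / (
            _CNP_CONTROL["C"] * ATOMIC_MASS["C"]
        )
        out[el] = math.log(c_percell * mass_ratio)
    return out


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate one full synthetic study with planted ground truth."""
    cfg = config or SyntheticConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_design, rng_el, rng_met, rng_voc, rng_blank, rng_is = (
        np.random.default_rng(s) for s in streams
    )

    n = cfg.n_per_group
    n_bio = 2 * n

    # --- biological samples -------------------------------------------------
    samples: list[SampleMeta] = []
    density_mean = {CONTROL: 1.5e5, HEAT: 1.3e5}
    for treatment in (CONTROL, HEAT):
        for rep in range(1, n + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"{treatment}-{rep}",
                    treatment=treatment,
                    biological_replicate=rep,
                    cell_density=float(
                        np.clip(
                            rng_design.normal(density_mean[treatment], 1.5e4),
                            5.0e4,
                            None,
                        )
                    ),
                    aliquot_volume=50.0,
                    dry_mass=float(
                        np.clip(rng_design.normal(0.010, 0.001), 0.003, None)
                    ),
                )
            )
    heat_ind = np.array([s.treatment == HEAT for s in samples], dtype=float)

    # --- analyte universes and differential sets ----------------------------
    el_names = _element_names(cfg.n_elements)
    met_names = [f"met_{i + 1:03d}" for i in range(cfg.n_metabolites)]
    voc_names = [f"voc_{i + 1:03d}" for i in range(cfg.n_volatiles)]
    n_contam = round(cfg.contaminant_fraction * cfg.n_volatiles)
    n_artefact = n_contam // 2
    contam_names = [f"siloxane_{i + 1:02d}" for i in range(n_artefact)] + [
        f"contam_{i + 1:02d}" for i in range(n_contam - n_artefact)
    ]

    stoich = (
        {e for e in ("C", "N", "P") if e in el_names}
        if cfg.plant_stoichiometry
        else set()
    )
    has_stoich = stoich == {"C", "N", "P"}

    shuffled_voc = list(rng_design.permutation(voc_names))
    unique_heat = set(shuffled_voc[: cfg.n_unique_heat])
    unique_control = set(
        shuffled_voc[cfg.n_unique_heat: cfg.n_unique_heat + cfg.n_unique_control]
    )
    shared_voc = [v for v in voc_names if v not in unique_heat | unique_control]

    def pick_differential(names: Sequence[str], n_layer: int, rng) -> list[str]:
        k = min(round(cfg.effect_fraction * n_layer), len(names))
        if k == 0:
            return []
        return sorted(rng.choice(list(names), size=k, replace=False).tolist())

    # differential counts are a fraction of the layer; shifted volatiles are
    # drawn from the shared set (structural absences are differential in
    # their own right and tracked separately)
    non_stoich = [e for e in el_names if e not in stoich]
    diff_el = pick_differential(non_stoich, len(non_stoich), rng_design)
    diff_met = pick_differential(met_names, cfg.n_metabolites, rng_design)
    diff_voc = pick_differential(shared_voc, cfg.n_volatiles, rng_design)

    # --- planted clusters over differential metabolites + shared volatiles --
    cluster_membership: dict[str, int] = {}
    if cfg.cluster_spec:
        met_pool = [f"metabolite:{m}" for m in diff_met]
        voc_pool = [f"volatile:{v}" for v in diff_voc]
        if sum(cfg.cluster_spec) > len(met_pool) + len(voc_pool):
            raise ValidationError(
                "infeasible cluster_spec: planted clusters need "
                f"{sum(cfg.cluster_spec)} differential analytes, only "
                f"{len(met_pool) + len(voc_pool)} available"
            )
        met_iter, voc_iter = iter(met_pool), iter(voc_pool)
        for k, size in enumerate(cfg.cluster_spec):
            members: list[str] = []
            if k == 0:
                # largest cluster is volatile-dominated with a couple of
                # metabolites, mirroring a mixed stress-response module
                for _ in range(min(2, size)):
                    m = next(met_iter, None) or next(voc_iter, None)
                    members.append(m)
                while len(members) < size:
                    m = next(voc_iter, None) or next(met_iter, None)
                    if m is None:
                        raise ValidationError("infeasible cluster_spec")
                    members.append(m)
            else:
                while len(members) < size:
                    m = next(met_iter, None) or next(voc_iter, None)
                    if m is None:
                        raise ValidationError("infeasible cluster_spec")
                    members.append(m)
            for m in members:
                cluster_membership[m] = k

    n_clusters = len(cfg.cluster_spec)
    factors = rng_design.standard_normal((n_clusters, n_bio)) if n_clusters else None

    # --- signed effect sizes -------------------------------------------------
    differential: dict[str, float] = {}

    def draw_beta(prefixed: str, rng) -> float:
        mag = abs(cfg.effect_size * rng.normal(1.0, 0.1))
        if prefixed in cluster_membership:
            sign = 1.0  # co-regulated modules respond in a common direction
        else:
            sign = 1.0 if rng.random() < 0.75 else -1.0
        return sign * mag

    for name in diff_el:
        differential[f"element:{name}"] = draw_beta(f"element:{name}", rng_el)
    for name in diff_met:
        differential[f"metabolite:{name}"] = draw_beta(f"metabolite:{name}", rng_met)
    for name in diff_voc:
        differential[f"volatile:{name}"] = draw_beta(f"volatile:{name}", rng_voc)
    if has_stoich:
        for el in ("C", "N"):
            differential[f"element:{el}"] = math.log(
                _CNP_HEAT[el] / _CNP_CONTROL[el]
            )

    lam_frac = math.sqrt(cfg.cluster_loading)
    res_frac = math.sqrt(1.0 - cfg.cluster_loading)

    def signal_matrix(layer: str, names: list[str], mus: np.ndarray, rng,
                      sigmas: np.ndarray) -> np.ndarray:
        """Per-cell log-abundance for the biological samples."""
        log_x = np.tile(mus[:, None], (1, n_bio))
        noise = rng.normal(0.0, 1.0, size=log_x.shape)
        for i, name in enumerate(names):
            prefixed = f"{layer}:{name}"
            beta = differential.get(prefixed, 0.0)
            log_x[i] += beta * heat_ind
            k = cluster_membership.get(prefixed)
            if k is not None and factors is not None:
                # split the within-group variance between the shared
                # factor and the residual (total stays sigma_a^2)
                log_x[i] += sigmas[i] * (
                    lam_frac * factors[k] + res_frac * noise[i]
                )
            else:
                log_x[i] += sigmas[i] * noise[i]
        return log_x

    bio_ids = [s.sample_id for s in samples]

    # --- elementome ----------------------------------------------------------
    stoich_mu = _stoich_percell_mu() if has_stoich else {}
    mus_el = np.array(
        [
            stoich_mu.get(name, rng_el.normal(math.log(1.0e-5), 1.0))
            for name in el_names
        ]
    )
    sig_el = np.array(
        [_SIGMA_STOICH if name in stoich else cfg.sigma for name in el_names]
    )
    percell_el = np.exp(signal_matrix("element", el_names, mus_el, rng_el, sig_el))
    conc = percell_el * np.array(
        [s.total_cells / s.dry_mass for s in samples]
    )  # ug per g dry mass
    elements = AnalyteTable(
        layer="element",
        abundance=pd.DataFrame(conc, index=el_names, columns=bio_ids),
        detected=pd.DataFrame(True, index=el_names, columns=bio_ids),
        samples=list(samples),
        ladder=[StepRecord("simulate", {"layer": "element", "seed": cfg.seed})],
    )

    # --- metabolome ----------------------------------------------------------
    mus_met = rng_met.normal(math.log(1.0e-3), 1.0, size=cfg.n_metabolites)
    percell_met = np.exp(
        signal_matrix("metabolite", met_names, mus_met, rng_met,
                      np.full(cfg.n_metabolites, cfg.sigma))
    )
    met_is = pd.Series(
        _IS_NOMINAL * np.exp(rng_is.normal(0.0, cfg.cv_internal_standard, n_bio)),
        index=bio_ids,
        name="is_area",
    )
    met_area = (
        percell_met
        * np.array([s.total_cells for s in samples])
        * (met_is.to_numpy() / _IS_NOMINAL)
    )
    metabolites = AnalyteTable(
        layer="metabolite",
        abundance=pd.DataFrame(met_area, index=met_names, columns=bio_ids),
        detected=pd.DataFrame(True, index=met_names, columns=bio_ids),
        samples=list(samples),
        ladder=[StepRecord("simulate", {"layer": "metabolite", "seed": cfg.seed})],
    )

    # --- volatilome (technical duplicates + contaminants) --------------------
    mus_voc = rng_voc.normal(math.log(1.0e-4), 1.5, size=cfg.n_volatiles)
    percell_voc = np.exp(
        signal_matrix("volatile", voc_names, mus_voc, rng_voc,
                      np.full(cfg.n_volatiles, cfg.sigma))
    )

    voc_samples: list[SampleMeta] = []
    for s in samples:
        for d in range(1, cfg.n_technical_reps + 1):
            voc_samples.append(
                replace(
                    s,
                    sample_id=f"{s.sample_id}.t{d}",
                    technical_replicate=d,
                )
            )
    voc_ids = [s.sample_id for s in voc_samples]
    n_meas = len(voc_ids)

    voc_is = pd.Series(
        _IS_NOMINAL * np.exp(rng_is.normal(0.0, cfg.cv_internal_standard, n_meas)),
        index=voc_ids,
        name="is_area",
    )

    all_voc_names = voc_names + contam_names
    area = np.zeros((len(all_voc_names), n_meas))
    detected = np.ones_like(area, dtype=bool)

    tech_noise = np.exp(
        rng_voc.normal(0.0, cfg.cv_technical, size=(cfg.n_volatiles, n_meas))
    )
    for j, meta in enumerate(voc_samples):
        bio_j = bio_ids.index(meta.sample_id.split(".")[0])
        area[: cfg.n_volatiles, j] = (
            percell_voc[:, bio_j]
            * meta.cell_density
            * tech_noise[:, j]
            * (voc_is.iloc[j] / _IS_NOMINAL)
        )

    # detection: dropout for the low-abundance half, structural absences
    log_percell = np.log(percell_voc)
    below_median = log_percell < np.median(log_percell, axis=1, keepdims=True)
    for i, name in enumerate(voc_names):
        for j, meta in enumerate(voc_samples):
            bio_j = bio_ids.index(meta.sample_id.split(".")[0])
            treatment = meta.treatment
            if name in unique_heat and treatment == CONTROL:
                detected[i, j] = False
            elif name in unique_control and treatment == HEAT:
                detected[i, j] = False
            elif below_median[i, bio_j] and rng_voc.random() < cfg.detection_dropout:
                detected[i, j] = False

    # contaminants: medium background, same level in samples and blanks
    mu_contam = rng_blank.normal(math.log(5.0e2), 0.5, size=n_contam)
    for i in range(n_contam):
        row = cfg.n_volatiles + i
        area[row] = np.exp(rng_blank.normal(mu_contam[i], 0.8, size=n_meas)) * (
            voc_is.to_numpy() / _IS_NOMINAL
        )

    classes = pd.Series(
        list(rng_design.choice(_VOC_CLASSES, size=cfg.n_volatiles))
        + ["siloxane"] * n_contam,
        index=all_voc_names,
    )
    volatiles = AnalyteTable(
        layer="volatile",
        abundance=pd.DataFrame(area, index=all_voc_names, columns=voc_ids),
        detected=pd.DataFrame(detected, index=all_voc_names, columns=voc_ids),
        samples=voc_samples,
        analyte_class=classes,
        ladder=[StepRecord("simulate", {"layer": "volatile", "seed": cfg.seed})],
    )

    # --- water blanks ---------------------------------------------------------
    blank_samples = [
        SampleMeta(
            sample_id=f"blank-{b + 1}",
            treatment=None,
            biological_replicate=None,
            is_blank=True,
        )
        for b in range(cfg.n_blanks)
    ]
    blank_ids = [s.sample_id for s in blank_samples]
    blank_area = np.zeros((len(all_voc_names), cfg.n_blanks))
    blank_det = np.zeros_like(blank_area, dtype=bool)
    blank_is = pd.Series(
        _IS_NOMINAL
        * np.exp(rng_is.normal(0.0, cfg.cv_internal_standard, cfg.n_blanks)),
        index=blank_ids,
        name="is_area",
    )
    for i in range(n_contam):
        row = cfg.n_volatiles + i
        blank_area[row] = np.exp(
            rng_blank.normal(mu_contam[i], 0.8, size=cfg.n_blanks)
        ) * (blank_is.to_numpy() / _IS_NOMINAL)
        blank_det[row] = True
    blanks = AnalyteTable(
        layer="volatile",
        abundance=pd.DataFrame(blank_area, index=all_voc_names, columns=blank_ids),
        detected=pd.DataFrame(blank_det, index=all_voc_names, columns=blank_ids),
        samples=blank_samples,
        analyte_class=classes,
        ladder=[StepRecord("simulate", {"layer": "blank", "seed": cfg.seed})],
    )

    truth = SyntheticTruth(
        differential=differential,
        cluster_membership=cluster_membership,
        contaminant_ids=set(contam_names),
        known_artefact_ids={c for c in contam_names if c.startswith("siloxane")},
        unique_to_heat_ids=unique_heat,
        unique_to_control_ids=unique_control,
        analyte_universe=(
            {f"element:{e}" for e in el_names}
            | {f"metabolite:{m}" for m in met_names}
            | {f"volatile:{v}" for v in all_voc_names}
        ),
    )
    return SyntheticStudy(
        config=cfg,
        samples=samples,
        elements=elements,
        metabolites=metabolites,
        volatiles=volatiles,
        blanks=blanks,
        metabolite_is=met_is,
        volatile_is=voc_is,
        blank_is=blank_is,
        known_artefacts=sorted(truth.known_artefact_ids),
        truth=truth,
    )


# --------------------------------------------------------------------------
# recovery metrics


def adjusted_rand_index(labels_a: Mapping[str, int], labels_b: Mapping[str, int]) -> float:
    """Adjusted Rand index between two labelings of the same item set."""
    items = sorted(labels_a)
    if set(items) != set(labels_b):
        raise ValidationError("labelings cover different item sets")
    a = pd.Series({i: labels_a[i] for i in items})
    b = pd.Series({i: labels_b[i] for i in items})
    contingency = pd.crosstab(a, b).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(contingency).sum()
    sum_a = comb(contingency.sum(axis=1)).sum()
    sum_b = comb(contingency.sum(axis=0)).sum()
    total = comb(len(items))
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    false_discovery_proportion: float
    ari: float | None  # None when no clusters were planted
    n_called: int
    n_true: int


def truth_recovery_report(
    truth: SyntheticTruth,
    results,
    clusters=None,
) -> RecoveryReport:
    """Score recovered differential calls (and clusters) against truth.

    ``results`` are integrated-table test results with layer-prefixed
    analyte ids; significance calls outside the planted differential
    and unique-to-treatment sets count as false discoveries.  When
    ``clusters`` (a :class:`~chemomix.network.NetworkClusters`) is
    given, the adjusted Rand index compares planted cluster labels with
    recovered connected-component labels over the planted members;
    members missing from the recovered network become singletons.
    """
    called = {r.analyte_id for r in results if r.significant}
    universe = truth.analyte_universe
    unknown = {c for c in called if c not in universe}
    if unknown:
        raise ValidationError(f"results name analytes outside truth: {sorted(unknown)}")

    true_set = truth.differential_ids
    structural = {f"volatile:{v}" for v in truth.unique_to_heat_ids} | {
        f"volatile:{v}" for v in truth.unique_to_control_ids
    }
    tested = {r.analyte_id for r in results}
    denom = true_set & tested
    sensitivity = len(called & true_set) / len(denom) if denom else 0.0
    false = called - true_set - structural
    fdp = len(false) / len(called) if called else 0.0

    ari = None
    if clusters is not None and truth.cluster_membership:
        planted = dict(truth.cluster_membership)
        recovered: dict[str, int] = {}
        for idx, comp in enumerate(clusters.components):
            for node in comp:
                recovered[node] = idx
        next_label = len(clusters.components)
        rec_on_members = {}
        for member in planted:
            if member in recovered:
                rec_on_members[member] = recovered[member]
            else:
                rec_on_members[member] = next_label
                next_label += 1
        ari = adjusted_rand_index(planted, rec_on_members)

    return RecoveryReport(
        sensitivity=float(sensitivity),
        false_discovery_proportion=float(fdp),
        ari=ari,
        n_called=len(called),
        n_true=len(true_set),
    )
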