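"""Synthetic imaging-flow-cytometry populations.

Real IFC exports are rarely shareable, so this module fabricates feature
tables with the statistical structure such data exhibits: a few hundred
numeric features of which only some carry class information, many
near-duplicates of those, plenty of pure noise, heavy-tailed intensity
distributions, strong class imbalance, and time-course / titration
experimental designs around a two-class (viable vs. apoptotic) system.

The generative model is deliberately simple and fully characterized:

* informative features are class-conditional unit-variance Gaussians
  whose class means differ by ``separation`` standard deviations, so the
  Bayes accuracy of the informative block has the closed form
  ``Phi(separation * sqrt(d) / 2)`` (equal-prior decision, d informative
  features) — usable as a benchmark ceiling;
* redundant features are random nonnegative unit-norm combinations of
  the informative ones plus Gaussian noise — near-duplicates that filter
  methods should score highly but mRMR should penalize;
* noise features are class-independent standard Gaussians;
* an optional XOR-style pair is jointly separable by the sign of its
  product while each marginal is class-symmetric — invisible to any
  univariate filter but a showcase for joint statistics;
* ``heavy_tail`` exponentiates all features, turning Gaussians into
  log-normals akin to fluorescence intensity channels.

Kinetics tables follow a logistic (sigmoid) apoptotic fraction over
time; titration tables use exact deterministic allocation.  Misleading
dye features reproduce two failure modes seen with real stains: a
*transient* channel whose apoptotic signal rises then decays (a
viability dye leaking out of destroyed cells), and an *early_switch*
channel that converts to the apoptotic distribution before the
class-defining morphology does (an executioner-caspase stain that
precedes morphological death) — perfectly separating the training
end-points yet biasing early-timepoint composition estimates upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .feature_table import FeatureTable

__all__ = [
    "PopulationSpec",
    "KineticsSpec",
    "TitrationSpec",
    "KineticsResult",
    "generate_population",
    "generate_kinetics",
    "generate_titration",
    "append_misleading_feature",
    "bayes_accuracy",
    "logistic_fraction",
]

VIABLE = "viable"
APOPTOTIC = "apoptotic"

#: separation (in sigma) of the misleading dye channel between its
#: "off" and "on" states; chosen large so the dye dominates end-point
#: training, as bright stains do
_DYE_SEPARATION = 6.0


@dataclass
class PopulationSpec:
    """Stated world for one simulated cell population.

    Defaults emulate a routine IFC experiment: 2000 cells, balanced
    classes, 5 informative morphology-like features at 2.5 sigma mean
    separation, 20 redundant near-copies, 75 pure-noise channels
    (100 features total, the order of magnitude IFC software exports).
    """

    m: int = 2000
    class_fractions: tuple[float, ...] = (0.5, 0.5)
    class_names: tuple[str, ...] = (VIABLE, APOPTOTIC)
    n_informative: int = 5
    n_redundant: int = 20
    n_noise: int = 75
    separation: float = 2.5
    redundancy_noise: float = 0.1
    heavy_tail: bool = False
    nonlinear_pair: bool = False
    seed: int = 0
    #: seed of the fixed feature structure (redundant mixing weights);
    #: defaults to ``seed``.  Series generators (kinetics, titration) pin
    #: it across tables so all draws share one simulated instrument.
    structure_seed: int | None = None

    def validate(self) -> None:
        fr = np.asarray(self.class_fractions, dtype=float)
        if len(fr) != len(self.class_names):
            raise ValueError("class_fractions and class_names length mismatch")
        if (fr < 0).any() or (fr > 1).any() or abs(fr.sum() - 1) > 1e-9:
            raise ValueError("class fractions must lie in [0,1] and sum to 1")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        total = self.n_informative + self.n_redundant + self.n_noise
        if total + (2 if self.nonlinear_pair else 0) < 1:
            raise ValueError("at least one feature required")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features require informative sources")


@dataclass
class KineticsSpec:
    """A stimulation time course with logistic apoptotic-fraction growth.

    Defaults echo a death-receptor stimulation experiment sampled at
    0-180 min with half-maximal killing at 60 min.
    """

    timepoints: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 120.0, 180.0)
    t50: float = 60.0
    slope: float = 0.05  # per minute
    cells_per_timepoint: int = 2000
    population: PopulationSpec = field(default_factory=PopulationSpec)
    misleading: str | None = None  # None | transient | early_switch
    seed: int = 0

    def validate(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if (tp < 0).any() or (np.diff(tp) <= 0).any():
            raise ValueError("timepoints must be non-negative and increasing")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.misleading not in (None, "transient", "early_switch"):
            raise ValueError(f"unknown misleading kind: {self.misleading}")
        self.population.validate()


@dataclass
class TitrationSpec:
    """Mixtures with experimentally adjusted apoptotic fractions."""

    mixture_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    cells_per_mixture: int = 1000
    population: PopulationSpec = field(default_factory=PopulationSpec)
    seed: int = 0

    def validate(self) -> None:
        fr = np.asarray(self.mixture_fractions, dtype=float)
        if (fr < 0).any() or (fr > 1).any():
            raise ValueError("mixture fractions must lie in [0, 1]")
        self.population.validate()


@dataclass
class KineticsResult:
    """Kinetics tables plus the ground truth needed to evaluate them.

    ``tables`` are unlabeled, as a real time course would be; the hidden
    per-cell labels and the generating logistic fractions are retained
    for evaluation only (never hand them to training code).
    """

    tables: list[FeatureTable]
    timepoints: list[float]
    true_fractions: list[float]
    hidden_labels: list[np.ndarray]
    misleading: str | None = None
    metadata: dict = field(default_factory=dict)


def logistic_fraction(t: np.ndarray | float, t50: float, slope: float):
    """Apoptotic fraction ``1 / (1 + exp(-slope (t - t50)))``."""
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(t, dtype=float) - t50)))


def bayes_accuracy(separation: float, n_informative: int) -> float:
    """Closed-form equal-prior Bayes accuracy of the informative block.

    Two unit-variance Gaussian classes whose means differ by
    ``separation`` on each of ``n_informative`` independent features are
    separated by distance ``separation * sqrt(d)``; the midpoint rule
    errs with probability ``Phi(-separation * sqrt(d) / 2)`` per class.
    Valid for the two-class generator before any heavy-tail transform
    (monotone transforms leave the optimal error unchanged but not the
    linear-classifier error).
    """
    if n_informative < 1:
        return 0.5
    return float(norm.cdf(0.5 * separation * np.sqrt(n_informative)))


def _feature_names(spec: PopulationSpec) -> list[str]:
    names = [f"inf_{i:03d}" for i in range(spec.n_informative)]
    names += [f"red_{i:03d}" for i in range(spec.n_redundant)]
    names += [f"noise_{i:03d}" for i in range(spec.n_noise)]
    if spec.nonlinear_pair:
        names += ["xor_a", "xor_b"]
    return names


def _draw_labels(
    rng: np.random.Generator, m: int, spec: PopulationSpec
) -> np.ndarray:
    return rng.choice(
        np.asarray(spec.class_names, dtype=object),
        size=m,
        p=np.asarray(spec.class_fractions, dtype=float),
    )


def _population_values(
    rng: np.random.Generator, labels: np.ndarray, spec: PopulationSpec
) -> np.ndarray:
    m = len(labels)
    class_index = np.array(
        [list(spec.class_names).index(lab) for lab in labels]
    )
    blocks = []
    informative = None
    if spec.n_informative:
        informative = rng.standard_normal((m, spec.n_informative))
        informative += spec.separation * class_index[:, None]
        blocks.append(informative)
    if spec.n_redundant:
        # fixed nonnegative unit-norm mixing weights per redundant column,
        # drawn from the structure seed so series of tables share them
        struct_seed = (
            spec.structure_seed if spec.structure_seed is not None else spec.seed
        )
        rng_struct = np.random.default_rng(struct_seed)
        weights = rng_struct.uniform(
            0.2, 1.0, (spec.n_informative, spec.n_redundant)
        )
        weights /= np.linalg.norm(weights, axis=0, keepdims=True)
        blocks.append(
            informative @ weights
            + spec.redundancy_noise * rng.standard_normal((m, spec.n_redundant))
        )
    if spec.n_noise:
        blocks.append(rng.standard_normal((m, spec.n_noise)))
    if spec.nonlinear_pair:
        sign = rng.choice([-1.0, 1.0], size=m)
        a = np.abs(rng.standard_normal(m))
        b = np.abs(rng.standard_normal(m))
        # first class: product > 0; others: product < 0; marginals symmetric
        flip = np.where(class_index == 0, 1.0, -1.0)
        blocks.append(np.column_stack([sign * a, sign * flip * b]))
    X = np.hstack(blocks)
    if spec.heavy_tail:
        X = np.exp(X)
    return X


def generate_population(spec: PopulationSpec) -> FeatureTable:
    """One labeled population table; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _draw_labels(rng, spec.m, spec)
    X = _population_values(rng, labels, spec)
    return FeatureTable(
        values=X,
        feature_names=_feature_names(spec),
        sample_ids=[f"cell_{i:06d}" for i in range(spec.m)],
        labels=labels,
        class_names=list(spec.class_names),
    )


def _spawn_seeds(seed: int, count: int) -> list[int]:
    """Independent child seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(count)]


def generate_kinetics(spec: KineticsSpec) -> KineticsResult:
    """Unlabeled time-course tables at logistic apoptotic fractions.

    Each timepoint's population is drawn from the two-class generator at
    the logistic fraction; the returned ``true_fractions`` are the
    generating logistic values.  A misleading dye column is appended when
    the spec requests one.
    """
    spec.validate()
    seeds = _spawn_seeds(spec.seed, len(spec.timepoints))
    tables, hidden, fractions = [], [], []
    for t, child_seed in zip(spec.timepoints, seeds):
        frac = float(logistic_fraction(t, spec.t50, spec.slope))
        pop = replace(
            spec.population,
            m=spec.cells_per_timepoint,
            class_fractions=(1.0 - frac, frac),
            seed=child_seed,
            structure_seed=(
                spec.population.structure_seed
                if spec.population.structure_seed is not None
                else spec.population.seed
            ),
        )
        labeled = generate_population(pop)
        hidden.append(labeled.labels.copy())
        fractions.append(frac)
        tables.append(
            FeatureTable(
                values=labeled.values,
                feature_names=list(labeled.feature_names),
                sample_ids=list(labeled.sample_ids),
            )
        )
    result = KineticsResult(
        tables=tables,
        timepoints=[float(t) for t in spec.timepoints],
        true_fractions=fractions,
        hidden_labels=hidden,
        metadata={"t50": spec.t50, "slope": spec.slope, "seed": spec.seed},
    )
    if spec.misleading is not None:
        result = append_misleading_feature(
            result, spec.misleading, seed=_spawn_seeds(spec.seed + 1, 1)[0]
        )
    return result


def generate_titration(spec: TitrationSpec) -> tuple[list[FeatureTable], list[float]]:
    """Labeled mixtures whose apoptotic counts match the request exactly.

    ``round(fraction * cells)`` rows are apoptotic (remainder viable) by
    deterministic allocation, mirroring experimentally adjusted ratios.
    """
    spec.validate()
    seeds = _spawn_seeds(spec.seed, len(spec.mixture_fractions))
    tables = []
    for frac, child_seed in zip(spec.mixture_fractions, seeds):
        m = spec.cells_per_mixture
        n_apo = int(round(frac * m))
        labels = np.array(
            [APOPTOTIC] * n_apo + [VIABLE] * (m - n_apo), dtype=object
        )
        rng = np.random.default_rng(child_seed)
        labels = labels[rng.permutation(m)]
        pop = replace(
            spec.population,
            m=m,
            seed=child_seed,
            structure_seed=(
                spec.population.structure_seed
                if spec.population.structure_seed is not None
                else spec.population.seed
            ),
        )
        # reuse the population machinery but with the exact label vector
        rng_vals = np.random.default_rng(child_seed + 1)
        X = _population_values(rng_vals, labels, pop)
        tables.append(
            FeatureTable(
                values=X,
                feature_names=_feature_names(pop),
                sample_ids=[f"cell_{i:06d}" for i in range(m)],
                labels=labels,
                class_names=[VIABLE, APOPTOTIC],
            )
        )
    return tables, [float(f) for f in spec.mixture_fractions]


def _transient_apoptotic_mean(t: np.ndarray, t50: float, slope: float):
    """Rise-then-fall profile of a leaking viability dye (peak near t50)."""
    rise = logistic_fraction(t, t50 / 2.0, 2.0 * slope)
    decay = np.exp(-np.maximum(np.asarray(t, dtype=float) - t50, 0.0) / t50)
    return _DYE_SEPARATION * rise * decay


def append_misleading_feature(
    result: KineticsResult,
    kind: str,
    seed: int = 0,
    lead_time: float = 30.0,
    feature_name: str = "caspase3_intensity",
) -> KineticsResult:
    """Append one misleading dye column to every kinetics table.

    ``transient``: the apoptotic-class mean of the new channel rises then
    falls over the time course (viable mean stays at 0), so late
    apoptotic cells look dye-negative.

    ``early_switch``: the channel jumps to its "on" distribution (mean 6,
    sd 1) following a logistic that leads the class-defining kinetics by
    ``lead_time`` minutes and is twice as steep (an executioner-protease
    signal precedes and sharpens relative to morphological death): every
    apoptotic cell is on, and viable cells are on with the probability
    needed to make total channel occupancy match the leading logistic.
    The channel separates the classes almost perfectly at the end points
    but overstates the apoptotic fraction at intermediate times.
    """
    if kind not in ("transient", "early_switch"):
        raise ValueError(f"unknown misleading kind: {kind}")
    t50 = result.metadata.get("t50", 60.0)
    slope = result.metadata.get("slope", 0.05)
    seeds = _spawn_seeds(seed, len(result.tables))
    new_tables = []
    for table, t, labels, child_seed in zip(
        result.tables, result.timepoints, result.hidden_labels, seeds
    ):
        rng = np.random.default_rng(child_seed)
        m = table.m
        apoptotic = np.asarray(labels, dtype=object) == APOPTOTIC
        col = rng.standard_normal(m)
        if kind == "transient":
            col[apoptotic] += float(_transient_apoptotic_mean(t, t50, slope))
        else:
            p_class = float(logistic_fraction(t, t50, slope))
            p_dye = float(logistic_fraction(t, t50 - lead_time, 2.0 * slope))
            col[apoptotic] += _DYE_SEPARATION
            excess = max(0.0, (p_dye - p_class) / max(1.0 - p_class, 1e-12))
            viable_on = (~apoptotic) & (rng.random(m) < excess)
            col[viable_on] += _DYE_SEPARATION
        values = np.column_stack([table.values, col])
        new_tables.append(
            FeatureTable(
                values=values,
                feature_names=list(table.feature_names) + [feature_name],
                sample_ids=list(table.sample_ids) if table.sample_ids else None,
                labels=table.labels.copy() if table.labels is not None else None,
                class_names=list(table.class_names),
            )
        )
    meta = dict(result.metadata)
    meta["misleading"] = {"kind": kind, "lead_time": lead_time, "seed": seed}
    return KineticsResult(
        tables=new_tables,
        timepoints=list(result.timepoints),
        true_fractions=list(result.true_fractions),
        hidden_labels=[lab.copy() for lab in result.hidden_labels],
        misleading=kind,
        metadata=meta,
    )
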