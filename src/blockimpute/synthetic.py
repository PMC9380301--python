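"""Synthetic cohort generator for block-structured clinical matrices.

The generator emulates the planned-missingness structure of a large
accelerated-longitudinal autism cohort: participants belong to diagnosis
(case / control) x enrolment-schedule groups, variables are organised into
overlapping subsets each acquired only for its eligible groups, and values
are driven by a shared latent-factor model so that variables correlate
within and across subsets — the structure multivariate imputation exploits.

Model
-----
Each participant draws a latent ``z ~ N(0, I_K)``. Variable ``j`` has
loadings ``w_j ~ N(0, loading_scale^2)^K`` and a per-group mean shift; its
raw value is ``intercept_j + w_j . z + shift[group] + noise``. Ordinal
variables are discretised into their level set by empirical quantiles of
the eligible participants' raw values, so level frequencies stay
non-degenerate. Cells outside a variable's eligible groups are structurally
absent: never generated, never imputed. Missingness is injected afterwards,
MCAR (independent Bernoulli per cell) or MAR (cell probability a logistic
function of a fully observed driver such as age, calibrated to the target
rate).

All randomness flows from a single master seed through named substreams
(loadings, latents, noise, demographics, mask), so a (config, seed) pair
reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import ClinicalMatrix, Subset, SubsetDesign, VariableSpec
from .exceptions import ConfigError

DIAGNOSES = ("case", "control")
SCHEDULES = ("child", "adolescent", "adult", "id_young", "id_old")

#: age range sampled per enrolment schedule, years
AGE_RANGES = {
    "child": (6.0, 12.0),
    "adolescent": (12.0, 18.0),
    "adult": (18.0, 30.0),
    "id_young": (12.0, 18.0),
    "id_old": (18.0, 30.0),
}


@dataclass(frozen=True)
class SubsetLayout:
    """Variable counts, eligible groups and target missingness for one
    subset of the design."""

    subset_id: int
    eligible_groups: tuple  # of (diagnosis, schedule) pairs
    n_nominal: int = 0
    n_continuous: int = 0
    n_ordinal: int = 0
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if not self.eligible_groups:
            raise ConfigError(f"subset {self.subset_id}: no eligible groups")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(
                f"subset {self.subset_id}: missing rate must be in [0, 1)"
            )

    @property
    def n_variables(self) -> int:
        return self.n_nominal + self.n_continuous + self.n_ordinal


@dataclass
class CohortConfig:
    """Full generative configuration for a synthetic cohort."""

    group_counts: dict  # (diagnosis, schedule) -> count
    subsets: list  # of SubsetLayout
    n_factors: int = 4
    loading_scale: float = 1.0
    noise_sd: float = 0.5
    group_shift_sd: float = 0.5
    #: sd of the per-diagnosis loading perturbation: cases and controls get
    #: different factor loadings, so variable-variable relationships differ
    #: by subgroup (clinical heterogeneity); 0 gives one global linear model
    diagnosis_loading_sd: float = 1.0
    intercept_loc: float = 10.0
    intercept_scale: float = 2.0
    #: right-skew of continuous variables: the standardized latent index is
    #: passed through (exp(s*u) - 1)/s, emulating the skewed, floor/ceiling
    #: shaped score distributions of clinical instruments; 0 keeps Gaussian
    continuous_skew: float = 0.7
    ordinal_levels: int = 4
    #: geometric decay of ordinal level frequencies (floor effect): level k
    #: gets mass ~ ordinal_floor_ratio**k; 1.0 gives uniform levels
    ordinal_floor_ratio: float = 0.6
    mechanism: str = "MCAR"
    mar_driver: str | None = None
    mar_slope: float = 1.0
    #: reserve the first continuous slot of the first subset for a
    #: schedule-linked, never-missing age variable (as in the emulated study)
    age_variable: bool = True
    #: variables that are never masked (fully observed by design)
    mask_exempt: tuple = ("age",)

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ConfigError("n_factors must be >= 1")
        if self.ordinal_levels < 2:
            raise ConfigError("ordinal_levels must be >= 2")
        if any(c < 0 for c in self.group_counts.values()):
            raise ConfigError("group counts must be >= 0")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "MAR" and not self.mar_driver:
            raise ConfigError("MAR mechanism needs a driver variable")

    @property
    def n_participants(self) -> int:
        return sum(self.group_counts.values())


@dataclass
class GroundTruth:
    """The complete (pre-masking) matrix and the injected missingness mask.

    Applying the mask to ``complete`` reproduces the emitted matrix exactly;
    structurally absent cells are absent in both."""

    complete: ClinicalMatrix
    mask: pd.DataFrame  # bool, True where a value was removed


# ---------------------------------------------------------------------------
# the packaged cohort layout
# ---------------------------------------------------------------------------

# Diagnosis x schedule counts solved to reproduce the printed subset sizes of
# the motivating cohort: 764 participants = 453 cases + 311 controls; 653
# excluding intellectual-disability schedules; 478 further excluding
# children; 458 children+adolescents+younger-ID participants.
_LEAP_GROUP_COUNTS = {
    ("case", "child"): 140,
    ("case", "adolescent"): 202,
    ("case", "adult"): 40,
    ("case", "id_young"): 28,
    ("case", "id_old"): 43,
    ("control", "child"): 35,
    ("control", "adolescent"): 38,
    ("control", "adult"): 198,
    ("control", "id_young"): 15,
    ("control", "id_old"): 25,
}


def _groups(diagnoses=DIAGNOSES, schedules=SCHEDULES, exclude=()):
    return tuple(
        (d, s)
        for d in diagnoses
        for s in schedules
        if (d, s) not in exclude
    )


def leap_like_config(participant_scale: float = 1.0) -> CohortConfig:
    """The packaged cohort configuration matching the motivating study's
    printed structure: 764 participants (453 cases / 311 controls), 160
    variables (2 fully observed nominals, 42 continuous, 116 ordinal) laid
    out over 15 overlapping subsets.

    ``participant_scale`` shrinks every group count proportionally (minimum
    2 per group) for scaled-down experiments; variable structure is kept.
    Per-subset missingness rates are placeholders in the 5-30% range, not
    calibrated to the study's (unpublished) table.
    """
    if participant_scale <= 0:
        raise ConfigError("participant_scale must be > 0")
    counts = {
        g: max(2, round(c * participant_scale)) if participant_scale != 1.0 else c
        for g, c in _LEAP_GROUP_COUNTS.items()
    }
    all_groups = _groups()
    cases = _groups(diagnoses=("case",))
    controls = _groups(diagnoses=("control",))
    non_id = _groups(schedules=("child", "adolescent", "adult"))
    s3_groups = controls + (("case", "child"), ("case", "adolescent"))
    layouts = [
        SubsetLayout(1, all_groups, 2, 10, 16, 0.05),
        SubsetLayout(2, cases, 0, 0, 8, 0.08),
        SubsetLayout(3, s3_groups, 0, 4, 26, 0.10),
        SubsetLayout(
            4,
            tuple(g for g in s3_groups if g != ("control", "adolescent")),
            0, 0, 6, 0.12,
        ),
        SubsetLayout(5, non_id, 0, 4, 0, 0.10),
        SubsetLayout(6, _groups(schedules=("adolescent", "adult")), 0, 8, 24, 0.25),
        SubsetLayout(
            7, _groups(schedules=("child", "adolescent", "id_young")),
            0, 1, 5, 0.12,
        ),
        SubsetLayout(
            8, (("case", "child"), ("case", "adolescent")), 0, 2, 4, 0.15
        ),
        SubsetLayout(9, _groups(schedules=("child", "adolescent")), 0, 2, 3, 0.18),
        SubsetLayout(10, _groups(schedules=("adult",)), 0, 2, 4, 0.20),
        SubsetLayout(11, _groups(schedules=("adolescent",)), 0, 2, 4, 0.15),
        SubsetLayout(12, (("case", "child"),), 0, 2, 4, 0.22),
        SubsetLayout(13, controls, 0, 2, 4, 0.10),
        SubsetLayout(
            14, (("control", "child"), ("control", "adolescent")), 0, 2, 3, 0.25
        ),
        SubsetLayout(15, _groups(schedules=("child",)), 0, 1, 5, 0.30),
    ]
    return CohortConfig(group_counts=counts, subsets=layouts)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _variable_plan(config: CohortConfig):
    """Yield (name, kind, subset_id) in design order. The first continuous
    variable of the first subset is the age variable; the nominal slots are
    sex then diagnosis."""
    nominal_names = iter(("sex", "diagnosis"))
    age_assigned = not config.age_variable
    for layout in config.subsets:
        for _ in range(layout.n_nominal):
            yield next(nominal_names), "nominal", layout.subset_id
        for i in range(layout.n_continuous):
            if not age_assigned:
                yield "age", "continuous", layout.subset_id
                age_assigned = True
            else:
                yield f"s{layout.subset_id:02d}_c{i + 1:02d}", "continuous", layout.subset_id
        for i in range(layout.n_ordinal):
            yield f"s{layout.subset_id:02d}_o{i + 1:02d}", "ordinal", layout.subset_id


def generate_cohort(config: CohortConfig, seed: int):
    """Draw a full synthetic cohort.

    Returns ``(matrix, design, truth)``: the emitted matrix with injected
    missingness, the subset design, and the ground truth (complete matrix +
    mask) for oracle evaluation.
    """
    master = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("loadings", "latents", "noise", "demographics", "mask"),
            master.spawn(5),
        )
    }

    # participants and group membership
    pid_group = []
    for (diag, sched), count in sorted(config.group_counts.items()):
        pid_group.extend([(diag, sched)] * count)
    n = len(pid_group)
    pids = [f"P{i + 1:04d}" for i in range(n)]
    groups = dict(zip(pids, pid_group))
    diag_arr = np.array([g[0] for g in pid_group])
    sched_arr = np.array([g[1] for g in pid_group])

    eligible = {}  # subset_id -> boolean row mask
    for layout in config.subsets:
        allowed = set(layout.eligible_groups)
        eligible[layout.subset_id] = np.array(
            [g in allowed for g in pid_group]
        )

    K = config.n_factors
    z = streams["latents"].standard_normal((n, K))
    rng_load = streams["loadings"]
    rng_noise = streams["noise"]
    rng_demo = streams["demographics"]

    group_keys = sorted(set(pid_group))
    group_index = np.array([group_keys.index(g) for g in pid_group])

    columns = {}
    specs = []
    structural = {}
    subset_vars = {layout.subset_id: [] for layout in config.subsets}

    for name, kind, sid in _variable_plan(config):
        rows = eligible[sid]
        col = np.full(n, np.nan)
        if kind == "nominal":
            if name == "sex":
                col[rows] = rng_demo.integers(0, 2, size=int(rows.sum())).astype(float)
            else:  # diagnosis
                col[rows] = (diag_arr[rows] == "case").astype(float)
            spec = VariableSpec(name, "nominal", levels=(0.0, 1.0), imputable=False)
        elif name == "age":
            ages = np.empty(int(rows.sum()))
            sub_scheds = sched_arr[rows]
            for sched, (lo, hi) in AGE_RANGES.items():
                pick = sub_scheds == sched
                ages[pick] = rng_demo.uniform(lo, hi, size=int(pick.sum()))
            col[rows] = ages
            spec = VariableSpec(name, "continuous")
        else:
            w = rng_load.normal(0.0, config.loading_scale, size=K)
            delta = rng_load.normal(0.0, config.diagnosis_loading_sd, size=K)
            shifts = rng_load.normal(0.0, config.group_shift_sd, size=len(group_keys))
            is_case = (diag_arr == "case").astype(float)
            raw = z @ w + is_case * (z @ delta) + shifts[group_index]
            raw = raw + rng_noise.normal(0.0, config.noise_sd, size=n)
            if kind == "continuous":
                intercept = rng_load.normal(
                    config.intercept_loc, config.intercept_scale
                )
                vals = raw[rows]
                s = config.continuous_skew
                if s > 0:
                    std = vals.std() or 1.0
                    vals = (np.expm1(s * (vals - vals.mean()) / std) / s) * std
                col[rows] = intercept + vals
                spec = VariableSpec(name, "continuous")
            else:
                L = config.ordinal_levels
                vals = raw[rows]
                weights = config.ordinal_floor_ratio ** np.arange(L)
                cum = np.cumsum(weights / weights.sum())[:-1]
                qs = np.quantile(vals, cum)
                col[rows] = np.digitize(vals, qs).astype(float)
                spec = VariableSpec(
                    name, "ordinal", levels=tuple(float(v) for v in range(L))
                )
        columns[name] = col
        specs.append(spec)
        structural[name] = ~rows
        subset_vars[sid].append(name)

    values = pd.DataFrame(columns, index=pids)
    struct_frame = pd.DataFrame(structural, index=pids)
    complete = ClinicalMatrix(values, specs, struct_frame)

    design = SubsetDesign(
        subsets=[
            Subset(
                subset_id=layout.subset_id,
                participants=frozenset(
                    pid for pid, keep in zip(pids, eligible[layout.subset_id]) if keep
                ),
                variables=tuple(subset_vars[layout.subset_id]),
                group_label="+".join(
                    sorted({f"{d}/{s}" for d, s in layout.eligible_groups})
                ),
            )
            for layout in config.subsets
        ],
        groups={pid: {"diagnosis": d, "schedule": s} for pid, (d, s) in groups.items()},
    )

    rates = {layout.subset_id: layout.missing_rate for layout in config.subsets}
    emitted, mask = inject_missingness(
        complete,
        design,
        rates,
        mechanism=config.mechanism,
        driver=config.mar_driver,
        slope=config.mar_slope,
        seed=int(streams["mask"].integers(0, 2**31 - 1)),
        exempt=config.mask_exempt,
    )
    return emitted, design, GroundTruth(complete=complete, mask=mask)


def inject_missingness(
    complete: ClinicalMatrix,
    design: SubsetDesign,
    rates,
    mechanism: str = "MCAR",
    driver: str | None = None,
    slope: float = 1.0,
    seed: int = 0,
    exempt=(),
):
    """Remove values from a complete matrix.

    ``rates`` is a scalar or a dict subset_id -> rate. MCAR masks each
    eligible cell independently at the subset's rate; MAR makes the cell
    probability ``expit(a + slope * driver_std)`` with the intercept ``a``
    calibrated per subset so the expected rate matches the target.

    Non-imputable variables, exempt variables, the driver, and structurally
    absent cells are never masked. Returns ``(matrix, mask)``.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ConfigError(f"unknown mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    values = complete.values.copy()
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    exempt = set(exempt)

    if mechanism == "MAR":
        if driver is None:
            raise ConfigError("MAR mechanism needs a driver variable")
        drv = complete.values[driver]
        if drv.isna().any() and not (
            complete.structural[driver][drv.isna()].all()
        ):
            raise ConfigError("MAR driver has missing values")

    for s in design.subsets:
        rate = rates[s.subset_id] if isinstance(rates, dict) else float(rates)
        if not 0.0 <= rate < 1.0:
            raise ConfigError(f"subset {s.subset_id}: rate {rate} out of [0, 1)")
        if rate == 0.0:
            continue
        pids = [p for p in values.index if p in s.participants]
        maskable = [
            v
            for v in s.variables
            if complete.spec(v).imputable and v not in exempt and v != driver
        ]
        if not maskable:
            continue
        if mechanism == "MCAR":
            prob = np.full(len(pids), rate)
        else:
            d = complete.values.loc[pids, driver].to_numpy()
            d_std = (d - d.mean()) / (d.std() or 1.0)

            def realised(a, d_std=d_std):
                return expit(a + slope * d_std).mean() - rate

            a_star = brentq(realised, -40.0, 40.0)
            prob = expit(a_star + slope * d_std)
        for v in maskable:
            cell_ok = ~complete.structural.loc[pids, v].to_numpy()
            draw = rng.random(len(pids)) < prob
            hit = draw & cell_ok
            hit_ids = np.array(pids)[hit]
            mask.loc[hit_ids, v] = True
            values.loc[hit_ids, v] = np.nan

    return ClinicalMatrix(values, list(complete.specs), complete.structural.copy()), mask
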