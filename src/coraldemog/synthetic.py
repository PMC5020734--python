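"""Ground-truth generators and survey emulation for end-to-end testing.

No usable public size-frequency dataset accompanies this kind of irregular
reef monitoring, so the package carries its own generator: it draws a
structured transition matrix, projects a known trajectory, and then degrades
it the way a real video-transect survey would — uneven transect effort
across years, missing survey years, binomial under-detection of the smallest
colonies (roughly half of them are overlooked on imagery), and optional
Poisson count noise. Every downstream stage can then be validated against a
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import RecruitmentSpec
from .structure import (LifeCycleStructure, SizeClassScheme, StructureError,
                        TransitionMatrix)

__all__ = [
    "GroundTruth",
    "ObservationModel",
    "generate_true_matrix",
    "simulate_series",
    "emulate_survey",
]


@dataclass(frozen=True)
class GroundTruth:
    """A known transition matrix plus the inputs that drive its trajectory."""

    matrix: TransitionMatrix
    initial_vector: np.ndarray
    recruitment: RecruitmentSpec = field(
        default_factory=lambda: RecruitmentSpec.deterministic())
    seed: int = 0

    def __post_init__(self) -> None:
        n0 = np.asarray(self.initial_vector, dtype=float)
        if np.any(n0 < 0):
            raise ValueError("initial vector must be nonnegative")
        if n0.shape != (self.matrix.n_classes,):
            raise ValueError("initial vector length does not match matrix")
        object.__setattr__(self, "initial_vector", n0)


def _default_effort() -> dict[int, int]:
    # the study-like sampling pattern: a thin post-disturbance survey year
    # followed by fuller effort, with a two-year gap
    return {2010: 3, 2013: 6, 2014: 6}


@dataclass(frozen=True)
class ObservationModel:
    """How a true abundance series is degraded into survey counts.

    ``transects_per_year`` maps survey year to transect count; the true
    series is taken to be expressed at ``reference_transects`` worth of
    effort, so observed counts scale by transects / reference_transects.
    SC1 colonies are detected with probability ``sc1_detection_prob``
    (binomial thinning by default, deterministic scaling when
    ``deterministic_detection`` is set, for exact tests).
    """

    transects_per_year: dict[int, int] = field(default_factory=_default_effort)
    transect_area_m2: float = 50.0
    reference_transects: int = 6
    sc1_detection_prob: float = 0.5
    count_noise: str = "none"  # none | poisson
    missing_years: frozenset[int] = frozenset({2011, 2012})
    deterministic_detection: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.sc1_detection_prob <= 1.0):
            raise ValueError("sc1 detection probability must be in (0, 1]")
        if self.transect_area_m2 <= 0:
            raise ValueError("transect area must be positive")
        if self.reference_transects < 1:
            raise ValueError("reference transect count must be >= 1")
        if any(c < 0 for c in self.transects_per_year.values()):
            raise ValueError("transect counts must be nonnegative")
        if self.count_noise not in ("none", "poisson"):
            raise ValueError("count_noise must be 'none' or 'poisson'")
        object.__setattr__(self, "missing_years", frozenset(self.missing_years))


def generate_true_matrix(structure: LifeCycleStructure,
                         survival_cap: float = 0.95,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         fertility_range: tuple[float, float] = (0.05, 0.3),
                         ) -> TransitionMatrix:
    """Draw a random transition matrix respecting a life-cycle graph.

    Per column, total survival (stasis + outgoing growth + shrinkage) is
    drawn in (0.7, 1.0) x survival_cap and split among the column's
    survival arcs with a stasis-weighted Dirichlet (weights 4 stasis,
    2 growth, 1 shrinkage): massive corals grow slowly relative to the
    width of their size bins, so persistence dominates annual transitions.
    Fertility entries are uniform in ``fertility_range`` (low, matching
    weak local recruitment). Deterministic for a fixed seed.
    """
    if not (0.0 < survival_cap <= 1.0):
        raise ValueError("survival_cap must be in (0, 1]")
    if not isinstance(structure, LifeCycleStructure):
        raise StructureError("structure must be a LifeCycleStructure")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = structure.n_classes
    M = np.zeros((k, k))
    surv_arcs_by_col: dict[int, list] = {j: [] for j in range(k)}
    for arc in structure.sorted_arcs():
        if arc.role == "fertility":
            M[arc.target, arc.source] = rng.uniform(*fertility_range)
        else:
            surv_arcs_by_col[arc.source].append(arc)
    for j, arcs in surv_arcs_by_col.items():
        if not arcs:
            continue
        total = survival_cap * rng.uniform(0.7, 1.0)
        alpha = {"stasis": 4.0, "growth": 2.0, "shrinkage": 1.0}
        shares = rng.dirichlet([alpha[a.role] for a in arcs])
        for arc, s in zip(arcs, shares):
            M[arc.target, arc.source] = total * s
    return TransitionMatrix(values=M, structure=structure)


def simulate_series(truth: GroundTruth, steps: int) -> np.ndarray:
    """True trajectory n(t+1) = M n(t) + v(t) over ``steps`` transitions.

    Only the deterministic recruit sequence of the truth's recruitment spec
    enters; abundances are real-valued (rounding to whole colonies happens
    only when a survey is emulated). Returns shape (steps + 1, k).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    from .projection import project_linear

    return project_linear(truth.matrix, truth.initial_vector, steps,
                          recruitment=truth.recruitment)


def emulate_survey(series, obs: ObservationModel, scheme: SizeClassScheme,
                   seed: int | None = None, years=None,
                   stratum: str = "2m") -> pd.DataFrame:
    """Degrade a true series into a long-format survey count table.

    ``years`` labels the rows of ``series`` (defaults to consecutive years
    starting at the smallest surveyed year). Only years with declared
    transect effort and not listed as missing produce output rows. Counts
    are scaled by effort share, SC1 is thinned at the detection
    probability, optional Poisson noise is applied, and results are rounded
    to whole colonies.
    """
    series = np.asarray(series, dtype=float)
    if np.any(series < 0):
        raise ValueError("true series must be nonnegative")
    if years is None:
        start = min(obs.transects_per_year) if obs.transects_per_year else 0
        years = [start + t for t in range(series.shape[0])]
    years = list(years)
    if len(years) != series.shape[0]:
        raise ValueError("years must label every series row")
    rng = np.random.default_rng(seed)
    cols = scheme.column_names()
    rows = []
    for year, n in zip(years, series):
        if year not in obs.transects_per_year or year in obs.missing_years:
            continue
        transects = obs.transects_per_year[year]
        counts = n * (transects / obs.reference_transects)
        if obs.deterministic_detection:
            counts = counts.copy()
            counts[0] *= obs.sc1_detection_prob
        elif obs.sc1_detection_prob < 1.0:
            counts = counts.copy()
            counts[0] = rng.binomial(int(round(counts[0])), obs.sc1_detection_prob)
        if obs.count_noise == "poisson":
            counts = rng.poisson(counts).astype(float)
        row = {"year": year, "stratum": stratum, "transects": transects,
               "unit": "raw", "imputed": False}
        row.update({c: float(np.round(v)) for c, v in zip(cols, counts)})
        rows.append(row)
    columns = ["year", "stratum", "transects", *cols, "unit", "imputed"]
    return pd.DataFrame(rows, columns=columns)
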