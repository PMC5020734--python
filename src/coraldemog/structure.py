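"""Size-class schemes, life-cycle constraint graphs and stage-transition matrices.

These are the domain objects shared by every stage of the pipeline: the
diameter bins that define the stage classification of coral colonies, the
graph of demographic transitions a model is allowed to use (stasis loops,
growth by one class, shrinkage, fertility into the smallest class), and the
estimated transition matrix together with its survival/fecundity split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Role",
    "Arc",
    "SizeClassScheme",
    "LifeCycleStructure",
    "TransitionMatrix",
    "MatrixDecomposition",
    "StructureError",
    "EmptySampleError",
    "UnidentifiableError",
    "read_structure_yaml",
    "write_structure_yaml",
    "read_matrix_csv",
    "write_matrix_csv",
]

# Tolerance used when checking that per-column survival probabilities sum to
# at most one; fertility entries are exempt from this bound.
SURVIVAL_SUM_TOL = 1e-9

ROLES = ("stasis", "growth", "shrinkage", "fertility")
Role = str


class StructureError(ValueError):
    """A matrix or arc set violates its declared life-cycle structure."""


class EmptySampleError(ValueError):
    """An operation that needs at least one observed colony received none."""


class UnidentifiableError(ValueError):
    """Fewer equations than free matrix parameters and no regularization."""


@dataclass(frozen=True)
class Arc:
    """One allowed transition: abundance moves from ``source`` to ``target``.

    Indices are 0-based internally; user-facing labels (SC1...) are 1-based.
    """

    target: int
    source: int
    role: Role

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise StructureError(f"unknown arc role {self.role!r}")
        if self.target < 0 or self.source < 0:
            raise StructureError("arc indices must be nonnegative")


@dataclass(frozen=True)
class SizeClassScheme:
    """Diameter bins for coral colonies plus a representative diameter per bin.

    The representative diameter (cm) is the single colony size used when
    converting class abundances into planar cover; the defaults are the bin
    midpoints, with 50 cm standing in for the open-ended largest class.
    """

    class_labels: tuple[str, ...] = ("SC1", "SC2", "SC3", "SC4", "SC5")
    lower_edges_cm: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0)
    upper_edges_cm: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, float("inf"))
    representative_diameter_cm: tuple[float, ...] = (2.5, 7.5, 15.0, 30.0, 50.0)

    def __post_init__(self) -> None:
        k = len(self.class_labels)
        if k < 2:
            raise ValueError("need at least 2 size classes")
        if not (len(self.lower_edges_cm) == len(self.upper_edges_cm)
                == len(self.representative_diameter_cm) == k):
            raise ValueError("scheme field lengths disagree")
        lo = np.asarray(self.lower_edges_cm)
        hi = np.asarray(self.upper_edges_cm)
        if not np.all(lo < hi):
            raise ValueError("each lower edge must be below its upper edge")
        if not np.all(lo[1:] > lo[:-1]) or not np.all(hi[1:] > hi[:-1]):
            raise ValueError("class edges must be strictly increasing")
        for d, a, b in zip(self.representative_diameter_cm, lo, hi):
            if not (a < d and (d < b or not np.isfinite(b))):
                raise ValueError(
                    f"representative diameter {d} outside class bounds ({a}, {b})")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def column_names(self) -> list[str]:
        """Lower-cased labels used as count columns in survey tables."""
        return [lab.lower() for lab in self.class_labels]


@dataclass(frozen=True)
class LifeCycleStructure:
    """Constraint graph of allowed transitions for a k-class stage model.

    Role placement is enforced: stasis only on the diagonal, growth only one
    class up, shrinkage only one class down, fertility only into class 1 from
    a larger class.
    """

    n_classes: int
    arcs: frozenset[Arc]

    def __post_init__(self) -> None:
        k = self.n_classes
        if k < 2:
            raise StructureError("need at least 2 classes")
        seen: set[tuple[int, int]] = set()
        for arc in self.arcs:
            i, j = arc.target, arc.source
            if i >= k or j >= k:
                raise StructureError(f"arc {arc} outside a {k}-class model")
            if (i, j) in seen:
                raise StructureError(f"duplicate arc at position ({i}, {j})")
            seen.add((i, j))
            ok = {
                "stasis": i == j,
                "growth": i == j + 1,
                "shrinkage": i == j - 1,
                "fertility": i == 0 and j > 0,
            }[arc.role]
            if not ok:
                raise StructureError(
                    f"role {arc.role!r} not allowed at position ({i}, {j})")

    @classmethod
    def from_arcs(cls, n_classes: int, arcs: Iterable[Arc]) -> "LifeCycleStructure":
        return cls(n_classes=n_classes, arcs=frozenset(arcs))

    @classmethod
    def default_graph(cls, n_classes: int = 5) -> "LifeCycleStructure":
        """Stasis in every class, growth by one class, shrinkage of the top
        class into the one below, fertility from the two largest classes.

        For five classes this is the canonical massive-coral life cycle with
        12 free parameters.
        """
        k = n_classes
        arcs = [Arc(i, i, "stasis") for i in range(k)]
        arcs += [Arc(i + 1, i, "growth") for i in range(k - 1)]
        arcs.append(Arc(k - 2, k - 1, "shrinkage"))
        arcs += [Arc(0, j, "fertility") for j in (k - 2, k - 1)]
        return cls.from_arcs(k, arcs)

    @classmethod
    def stasis_only(cls, n_classes: int) -> "LifeCycleStructure":
        return cls.from_arcs(n_classes, [Arc(i, i, "stasis") for i in range(n_classes)])

    @property
    def n_parameters(self) -> int:
        return len(self.arcs)

    def sorted_arcs(self) -> list[Arc]:
        """Deterministic arc ordering (column-major, then row)."""
        return sorted(self.arcs, key=lambda a: (a.source, a.target))

    def role_mask(self, roles: Sequence[Role]) -> np.ndarray:
        m = np.zeros((self.n_classes, self.n_classes), dtype=bool)
        for arc in self.arcs:
            if arc.role in roles:
                m[arc.target, arc.source] = True
        return m

    def allowed_mask(self) -> np.ndarray:
        return self.role_mask(ROLES)

    def survival_mask(self) -> np.ndarray:
        return self.role_mask(("stasis", "growth", "shrinkage"))


def _check_matrix(values: np.ndarray, structure: LifeCycleStructure) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    k = structure.n_classes
    if values.shape != (k, k):
        raise StructureError(f"matrix shape {values.shape} != ({k}, {k})")
    if np.any(values < 0):
        raise StructureError("matrix entries must be nonnegative")
    if np.any(values[~structure.allowed_mask()] != 0):
        raise StructureError("nonzero entry on a forbidden arc")
    surv_sums = np.where(structure.survival_mask(), values, 0.0).sum(axis=0)
    if np.any(surv_sums > 1.0 + SURVIVAL_SUM_TOL):
        raise StructureError(
            f"column survival sums exceed 1: {surv_sums.max():.12f}")
    return values


@dataclass(frozen=True)
class TransitionMatrix:
    """A k x k stage-transition (Leslie-type) matrix under a constraint graph.

    Survival entries (stasis + growth + shrinkage) in each column are
    probabilities and must sum to at most one; first-row fertility entries
    are per-capita recruit contributions and are only required nonnegative.
    """

    values: np.ndarray
    structure: LifeCycleStructure
    scheme: SizeClassScheme | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_matrix(self.values, self.structure))

    @property
    def n_classes(self) -> int:
        return self.structure.n_classes

    def survival_column_sums(self) -> np.ndarray:
        return np.where(self.structure.survival_mask(), self.values, 0.0).sum(axis=0)

    def dominant_eigenvalue(self) -> float:
        # diagnostic only; asymptotic eigen-growth is not a headline output
        return float(np.max(np.abs(np.linalg.eigvals(self.values))))


@dataclass(frozen=True)
class MatrixDecomposition:
    """Split of M into survival S (stasis/growth/shrinkage) and fecundity R.

    The supports are disjoint and S + R = M exactly, entry for entry.
    """

    S: np.ndarray
    R: np.ndarray
    structure: LifeCycleStructure = field(
        default_factory=lambda: LifeCycleStructure.default_graph())

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        R = np.asarray(self.R, dtype=float)
        if S.shape != R.shape or S.shape[0] != S.shape[1]:
            raise StructureError("S and R must be square and of equal shape")
        if np.any((S != 0) & (R != 0)):
            raise StructureError("S and R must have disjoint supports")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "R", R)

    @property
    def M(self) -> np.ndarray:
        return self.S + self.R

    @property
    def n_classes(self) -> int:
        return self.S.shape[0]


# ---------------------------------------------------------------------------
# On-disk formats: structure YAML (list of labelled arcs) and matrix CSV
# (class labels as header and index, row-major values).
# ---------------------------------------------------------------------------

def write_structure_yaml(structure: LifeCycleStructure, path,
                         labels: Sequence[str] | None = None) -> None:
    labels = list(labels) if labels is not None else [
        f"SC{i + 1}" for i in range(structure.n_classes)]
    doc = {
        "classes": labels,
        "arcs": [
            {"from": labels[a.source], "to": labels[a.target], "role": a.role}
            for a in structure.sorted_arcs()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_structure_yaml(path) -> LifeCycleStructure:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    labels = list(doc["classes"])
    index = {lab: i for i, lab in enumerate(labels)}
    arcs = [Arc(index[a["to"]], index[a["from"]], a["role"]) for a in doc["arcs"]]
    return LifeCycleStructure.from_arcs(len(labels), arcs)


def write_matrix_csv(matrix: TransitionMatrix, path,
                     labels: Sequence[str] | None = None) -> None:
    import pandas as pd

    labels = list(labels) if labels is not None else (
        list(matrix.scheme.class_labels) if matrix.scheme is not None
        else [f"SC{i + 1}" for i in range(matrix.n_classes)])
    pd.DataFrame(matrix.values, index=labels, columns=labels).to_csv(path)


def read_matrix_csv(path, structure: LifeCycleStructure | None = None,
                    scheme: SizeClassScheme | None = None) -> TransitionMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if structure is None:
        # infer the loosest structure consistent with the stored support
        k = values.shape[0]
        arcs = []
        for i in range(k):
            for j in range(k):
                if values[i, j] == 0:
                    continue
                if i == j:
                    arcs.append(Arc(i, j, "stasis"))
                elif i == j + 1:
                    arcs.append(Arc(i, j, "growth"))
                elif i == j - 1:
                    arcs.append(Arc(i, j, "shrinkage"))
                elif i == 0:
                    arcs.append(Arc(i, j, "fertility"))
                else:
                    raise StructureError(
                        f"entry at ({i}, {j}) fits no life-cycle role")
        structure = LifeCycleStructure.from_arcs(k, arcs)
    return TransitionMatrix(values=values, structure=structure, scheme=scheme)
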