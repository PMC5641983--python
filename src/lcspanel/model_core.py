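"""Path-model specification in RAM notation and model-implied moments.

A structural model over a set of observed and latent variables is held as a
:class:`ParameterTable`: one row per parameter, each row addressed to one of
three matrix slots,

``paths``
    directed regression weights (the RAM *A* matrix),
``covariances``
    variances and symmetric covariances (the RAM *S* matrix),
``means``
    intercepts and means (the RAM *M* vector).

Rows are either fixed at a numeric value or free with a start value and a
label.  Free rows that share a label share a single parameter (equality
constraint), which is how cross-wave loading/intercept equality and
multigroup equality are expressed; the free-parameter count used for degrees
of freedom collapses equality groups to one entry.

Given a parameter vector ``theta`` (one entry per distinct free label, in
order of first appearance), :func:`assemble` realizes the table as numeric
RAM matrices, and :func:`implied_moments` maps those to the model-implied
mean vector and covariance matrix of the observed variables:

    sigma = F (I - A)^{-1} S (I - A)^{-T} F^T
    mu    = F (I - A)^{-1} M

where F is the 0/1 selection matrix picking observed rows.  A single pair of
routines therefore serves every model family in :mod:`lcspanel.theory_models`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelSpecError",
    "StructuralCycleError",
    "VariableSet",
    "Parameter",
    "ParameterTable",
    "RAMMatrices",
    "CompiledModel",
    "assemble",
    "implied_moments",
    "model_df",
]

SLOTS = ("paths", "covariances", "means")

#: conventional "source" for mean rows (the constant triangle in path diagrams)
CONST = "1"


class ModelSpecError(ValueError):
    """Raised for ill-formed model specifications."""


class StructuralCycleError(ValueError):
    """Raised when (I - A) is singular, i.e. the directed paths form a cycle
    with unit total gain and the structural system has no reduced form."""


@dataclass(frozen=True)
class VariableSet:
    """Ordered variables of a model; ordering defines matrix row indices.

    Parameters
    ----------
    names:
        All variable names, observed and latent, in matrix order.
    latent:
        Subset of ``names`` that are latent.
    """

    names: tuple[str, ...]
    latent: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "latent", frozenset(self.latent))
        if len(set(self.names)) != len(self.names):
            raise ModelSpecError("variable names must be unique")
        unknown = self.latent - set(self.names)
        if unknown:
            raise ModelSpecError(f"latent names not in variable list: {sorted(unknown)}")
        if not self.observed:
            raise ModelSpecError("at least one observed variable is required")

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n not in self.latent)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ModelSpecError(f"unknown variable {name!r}") from None


@dataclass(frozen=True)
class Parameter:
    """One row of a :class:`ParameterTable`.

    ``value`` is the fixed value when ``free`` is False and the start value
    when ``free`` is True.  For mean rows the source is the constant ``"1"``.
    """

    slot: str
    source: str
    target: str
    free: bool = True
    value: float = 0.0
    label: str | None = None

    @property
    def is_variance(self) -> bool:
        return self.slot == "covariances" and self.source == self.target


class ParameterTable:
    """Symbolic model specification: a variable set plus parameter rows."""

    def __init__(self, variables: VariableSet):
        self.variables = variables
        self.rows: list[Parameter] = []
        self._keys: set[tuple] = set()

    # -- construction -------------------------------------------------

    def add(self, slot, source, target, *, free=True, value=0.0, label=None):
        if slot not in SLOTS:
            raise ModelSpecError(f"unknown slot {slot!r}")
        if slot == "means":
            source = CONST
        else:
            self.variables.index(source)
        self.variables.index(target)
        key = self._key(slot, source, target)
        if key in self._keys:
            raise ModelSpecError(f"duplicate parameter row {key}")
        if slot == "covariances" and source == target and free and value <= 0:
            raise ModelSpecError(
                f"free variance of {source!r} needs a positive start value"
            )
        self._keys.add(key)
        self.rows.append(Parameter(slot, source, target, free, float(value), label))
        return self

    def path(self, source, target, **kw):
        """Directed regression of ``target`` on ``source``."""
        return self.add("paths", source, target, **kw)

    def cov(self, a, b=None, **kw):
        """(Co)variance row; ``cov(a)`` is the variance of ``a``."""
        return self.add("covariances", a, b if b is not None else a, **kw)

    def mean(self, target, **kw):
        """Mean/intercept row for ``target``."""
        return self.add("means", CONST, target, **kw)

    @staticmethod
    def _key(slot, source, target):
        if slot == "covariances":
            source, target = sorted((source, target))
        return (slot, source, target)

    # -- bookkeeping ---------------------------------------------------

    @property
    def free_labels(self) -> list[str]:
        """Distinct labels of free parameters, in order of first appearance.

        Rows without an explicit label get an auto-label derived from their
        position, so they are necessarily singleton groups.
        """
        seen: dict[str, None] = {}
        for row in self.rows:
            if row.free:
                seen.setdefault(self._label_of(row))
        return list(seen)

    @staticmethod
    def _label_of(row: Parameter) -> str:
        if row.label is not None:
            return row.label
        return f"{row.slot}:{row.source}->{row.target}"

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    def copy(self) -> "ParameterTable":
        out = ParameterTable(self.variables)
        out.rows = list(self.rows)
        out._keys = set(self._keys)
        return out

    def drop(self, slot, source, target) -> "ParameterTable":
        """Copy of the table without the addressed row."""
        key = self._key(slot, source, target)
        if key not in self._keys:
            raise ModelSpecError(f"no such row {key}")
        out = ParameterTable(self.variables)
        out.rows = [r for r in self.rows if self._key(r.slot, r.source, r.target) != key]
        out._keys = self._keys - {key}
        return out

    def fix(self, slot, source, target, value) -> "ParameterTable":
        """Copy of the table with the addressed row fixed at ``value``."""
        key = self._key(slot, source, target)
        out = self.copy()
        for i, r in enumerate(out.rows):
            if self._key(r.slot, r.source, r.target) == key:
                out.rows[i] = replace(r, free=False, value=float(value), label=None)
                return out
        raise ModelSpecError(f"no such row {key}")

    def relabel(self, mapping) -> "ParameterTable":
        """Copy with free-row labels rewritten through ``mapping(label) -> label``."""
        out = ParameterTable(self.variables)
        out._keys = set(self._keys)
        for r in self.rows:
            if r.free:
                out.rows.append(replace(r, label=mapping(self._label_of(r))))
            else:
                out.rows.append(r)
        return out

    def start_values(self) -> np.ndarray:
        """Start vector in free-label order (first row of each group wins)."""
        starts: dict[str, float] = {}
        for row in self.rows:
            if row.free:
                starts.setdefault(self._label_of(row), row.value)
        return np.array([starts[l] for l in self.free_labels])

    # -- realization ---------------------------------------------------

    def compile(self) -> "CompiledModel":
        return CompiledModel(self)

    def __len__(self):
        return len(self.rows)

    def __repr__(self):
        v = self.variables
        return (
            f"<ParameterTable {len(v.observed)} observed / {len(v.latent)} latent, "
            f"{len(self.rows)} rows, {self.n_free} free>"
        )

    # -- plain-text serialization -------------------------------------

    def to_text(self) -> str:
        """Serialize to the plain-text key-value format (one row per line)."""
        buf = io.StringIO()
        buf.write("# lcspanel model specification\n")
        for name in self.variables.names:
            role = "latent" if name in self.variables.latent else "observed"
            buf.write(f"variable\t{name}\t{role}\n")
        for r in self.rows:
            status = "free" if r.free else "fixed"
            label = r.label if r.label is not None else "."
            buf.write(
                f"{r.slot}\t{r.source}\t{r.target}\t{status}\t{r.value!r}\t{label}\n"
            )
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ParameterTable":
        names, latent, prows = [], set(), []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "variable":
                _, name, role = parts
                names.append(name)
                if role == "latent":
                    latent.add(name)
            else:
                slot, source, target, status, value, label = parts
                prows.append(
                    (slot, source, target, status == "free", float(value),
                     None if label == "." else label)
                )
        table = cls(VariableSet(tuple(names), frozenset(latent)))
        for slot, source, target, free, value, label in prows:
            table.add(slot, source, target, free=free, value=value, label=label)
        return table


@dataclass
class RAMMatrices:
    """Numeric realization of a model at one parameter point.

    ``A`` holds directed path weights (A[i, j] = weight of j -> i), ``S`` the
    symmetric (co)variances, ``M`` the means/intercepts, and ``obs_idx`` the
    row indices of observed variables (the F filter).
    """

    A: np.ndarray
    S: np.ndarray
    M: np.ndarray
    obs_idx: np.ndarray
    names: tuple[str, ...]

    @property
    def F(self) -> np.ndarray:
        F = np.zeros((len(self.obs_idx), len(self.names)))
        F[np.arange(len(self.obs_idx)), self.obs_idx] = 1.0
        return F

    def full_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Implied mean vector and covariance over ALL variables (latents
        included); used e.g. for change-score variance decompositions."""
        m = len(self.names)
        I_A = np.eye(m) - self.A
        try:
            B = np.linalg.inv(I_A)
        except np.linalg.LinAlgError:
            raise StructuralCycleError("I - A is singular") from None
        if not np.all(np.isfinite(B)):
            raise StructuralCycleError("I - A is numerically singular")
        sigma = B @ self.S @ B.T
        return B @ self.M, 0.5 * (sigma + sigma.T)


class CompiledModel:
    """Index-level realization plan for fast repeated assembly.

    Precomputes, per free parameter, the list of matrix cells it populates
    (equality-group members all point at the same theta entry), plus the base
    matrices of fixed values.  Shared by the optimizer's objective/gradient.
    """

    def __init__(self, spec: ParameterTable):
        v = spec.variables
        m = v.n
        self.spec = spec
        self.names = v.names
        self.nvar = m
        self.obs_idx = np.array([v.index(n) for n in v.observed], dtype=int)
        self.labels = spec.free_labels
        self.k = len(self.labels)
        pos = {l: i for i, l in enumerate(self.labels)}

        self.A0 = np.zeros((m, m))
        self.S0 = np.zeros((m, m))
        self.M0 = np.zeros(m)
        # placements[k] = list of ("A"|"S"|"M", i, j)
        self.placements: list[list[tuple[str, int, int]]] = [[] for _ in range(self.k)]
        self.is_variance = np.zeros(self.k, dtype=bool)

        for row in spec.rows:
            if row.slot == "paths":
                i, j = v.index(row.target), v.index(row.source)
                where = ("A", i, j)
                base = self.A0
            elif row.slot == "covariances":
                i, j = v.index(row.source), v.index(row.target)
                where = ("S", i, j)
                base = self.S0
            else:
                i, j = v.index(row.target), 0
                where = ("M", i, 0)
                base = None
            if row.free:
                idx = pos[ParameterTable._label_of(row)]
                self.placements[idx].append(where)
                if row.is_variance:
                    self.is_variance[idx] = True
            else:
                if where[0] == "M":
                    self.M0[i] = row.value
                elif where[0] == "S":
                    base[i, j] = base[j, i] = row.value
                else:
                    base[i, j] = row.value

    def matrices(self, theta: np.ndarray) -> RAMMatrices:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ModelSpecError(
                f"theta has length {theta.size}, model has {self.k} free parameters"
            )
        A, S, M = self.A0.copy(), self.S0.copy(), self.M0.copy()
        for t, places in zip(theta, self.placements):
            for kind, i, j in places:
                if kind == "A":
                    A[i, j] = t
                elif kind == "S":
                    S[i, j] = S[j, i] = t
                else:
                    M[i] = t
        return RAMMatrices(A, S, M, self.obs_idx, self.names)

    def start(self) -> np.ndarray:
        return self.spec.start_values()


def assemble(spec: ParameterTable | CompiledModel, theta) -> RAMMatrices:
    """Populate RAM matrices from a specification and a free-parameter vector.

    ``theta`` is ordered by first appearance of each free label; members of
    an equality group share one entry.
    """
    compiled = spec if isinstance(spec, CompiledModel) else spec.compile()
    return compiled.matrices(np.asarray(theta, dtype=float))


def implied_moments(ram: RAMMatrices) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix over observed variables."""
    mu_full, sigma_full = ram.full_moments()
    o = ram.obs_idx
    return mu_full[o], sigma_full[np.ix_(o, o)]


def model_df(spec: ParameterTable, observed_count: int | None = None) -> int:
    """Degrees of freedom: p(p+3)/2 observed moments minus free parameters.

    The mean structure is always counted as modeled (p means plus p(p+1)/2
    covariance cells).  Equality groups count as one parameter.
    """
    p = observed_count if observed_count is not None else len(spec.variables.observed)
    n_moments = p * (p + 3) // 2
    df = n_moments - spec.n_free
    if df < 0:
        raise ModelSpecError(
            f"over-parameterized: {spec.n_free} free parameters for {n_moments} moments"
        )
    return df
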