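"""Builders for the competing developmental models of two-wave cognition.

Three theories of cognitive development over two measurement waves of a
crystallized score (Vocabulary, ``voc``) and a fluid score (Matrix
Reasoning, ``mat``), each compiled to the shared latent-change-score (LCS)
machinery:

* **g factor** — a common factor at each wave explains both observed
  scores; change happens only at the level of g (no direct cross-domain
  paths).  Loadings are equality-constrained across waves (weak invariance)
  in the reference build.
* **investment** — fluid ability drives growth in crystallized ability:
  a single coupling path from wave-1 Matrix Reasoning to the Vocabulary
  change factor.
* **mutualism** — bidirectional coupling: each domain's wave-1 level feeds
  the other domain's change.

Every model decomposes the wave-2 score as Y2 = 1*Y1 + 1*dY with a latent
change factor dY carrying its own intercept (alpha), variance, self-feedback
(beta: dY on Y1) and optional couplings (gamma: dY on the other domain's
wave-1 score).  Age at wave 1 enters as a baseline covariate (centered at
its sample mean before fitting); in the g model it predicts the g factor
only, unless one of the alternative age placements is requested.

Free parameters carry canonical labels (``beta_voc``, ``gamma_voc_to_dmat``,
``alpha_mat``, ...) that the reporting layer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelSpecError, ParameterTable, VariableSet

__all__ = [
    "build_univariate_lcs",
    "build_bivariate_lcs",
    "build_g_model",
    "build_theory",
    "TheoryModelConfig",
    "MultigroupSpec",
    "apply_multigroup",
    "rescale_time2",
    "rescale_dataset",
    "REFERENCE_INTERVAL",
]

#: mean inter-test interval (years) used as the annualization reference
REFERENCE_INTERVAL = 1.48

_DOMAINS = {"vocabulary": "voc", "matrix": "mat"}


def _domain_code(domain: str) -> str:
    if domain in _DOMAINS:
        return _DOMAINS[domain]
    if domain in _DOMAINS.values():
        return domain
    raise ModelSpecError(f"unknown domain {domain!r}; expected vocabulary or matrix")


def build_univariate_lcs(domain: str, self_feedback: bool = True) -> ParameterTable:
    """Univariate LCS model for one domain: {age, Y1, Y2} observed, dY latent.

    Free parameters (8): age mean and variance; Y1 intercept, age slope and
    residual variance; dY intercept, variance and self-feedback beta (dY on
    Y1).  With ``self_feedback=False`` beta is fixed to 0 (7 free), the
    variant whose change intercept mirrors a paired-samples t test.
    """
    d = _domain_code(domain)
    y1, y2, dy = f"{d}1", f"{d}2", f"d_{d}"
    v = VariableSet(("age", y1, y2, dy), latent={dy})
    t = ParameterTable(v)
    t.path(y1, y2, free=False, value=1.0)
    t.path(dy, y2, free=False, value=1.0)
    t.path("age", y1, label=f"{y1}_on_age")
    if self_feedback:
        t.path(y1, dy, label=f"beta_{d}")
    t.cov("age", label="age_var", value=9.0)
    t.cov(y1, label=f"{y1}_resid_var", value=25.0)
    t.cov(dy, label=f"d{d}_var", value=5.0)
    t.mean("age", label="age_mean")
    t.mean(y1, label=f"{y1}_int", value=30.0)
    t.mean(dy, label=f"alpha_{d}")
    return t


def build_bivariate_lcs(
    couplings: frozenset | set | tuple = ("voc_to_dmat", "mat_to_dvoc"),
    age_on_change: bool = False,
    age_squared: str | None = None,
) -> ParameterTable:
    """Bivariate LCS model; the coupling set selects the theory.

    ``couplings`` is a subset of ``{"voc_to_dmat", "mat_to_dvoc"}``: both
    paths give the mutualism model (18 free parameters, df = 2), the single
    ``mat_to_dvoc`` path the investment model (17 free, df = 3), the empty
    set a couplings-free bivariate model (16 free, df = 4).

    ``age_on_change=True`` additionally lets age predict both change factors
    (+2 parameters).  ``age_squared`` adds a squared-age regressor on the
    wave-1 scores: ``"free"`` estimates the two quadratic slopes,
    ``"null"`` fixes them to 0 (the nested reference for the quadratic-age
    test); both include the regressor's own moments.
    """
    couplings = set(couplings)
    unknown = couplings - {"voc_to_dmat", "mat_to_dvoc"}
    if unknown:
        raise ModelSpecError(f"unknown couplings {sorted(unknown)}")
    names = ["age", "voc1", "mat1", "voc2", "mat2", "d_voc", "d_mat"]
    if age_squared is not None:
        names.insert(1, "age_sq")
    v = VariableSet(tuple(names), latent={"d_voc", "d_mat"})
    t = ParameterTable(v)
    for d in ("voc", "mat"):
        t.path(f"{d}1", f"{d}2", free=False, value=1.0)
        t.path(f"d_{d}", f"{d}2", free=False, value=1.0)
        t.path("age", f"{d}1", label=f"{d}1_on_age")
        t.path(f"{d}1", f"d_{d}", label=f"beta_{d}")
    if "voc_to_dmat" in couplings:
        t.path("voc1", "d_mat", label="gamma_voc_to_dmat")
    if "mat_to_dvoc" in couplings:
        t.path("mat1", "d_voc", label="gamma_mat_to_dvoc")
    if age_on_change:
        t.path("age", "d_voc", label="dvoc_on_age")
        t.path("age", "d_mat", label="dmat_on_age")
    if age_squared is not None:
        free = age_squared == "free"
        if age_squared not in ("free", "null"):
            raise ModelSpecError("age_squared must be None, 'free' or 'null'")
        t.path("age_sq", "voc1", free=free, value=0.0,
               label="voc1_on_age_sq" if free else None)
        t.path("age_sq", "mat1", free=free, value=0.0,
               label="mat1_on_age_sq" if free else None)
        t.cov("age_sq", label="age_sq_var", value=50.0)
        t.cov("age", "age_sq", label="age_age_sq_cov")
        t.mean("age_sq", label="age_sq_mean", value=9.0)
    t.cov("age", label="age_var", value=9.0)
    t.cov("voc1", label="voc1_resid_var", value=50.0)
    t.cov("mat1", label="mat1_resid_var", value=9.0)
    t.cov("voc1", "mat1", label="wave1_resid_cov")
    t.cov("d_voc", label="dvoc_var", value=10.0)
    t.cov("d_mat", label="dmat_var", value=3.0)
    t.cov("d_voc", "d_mat", label="change_resid_cov")
    t.mean("age", label="age_mean")
    t.mean("voc1", label="voc1_int", value=55.0)
    t.mean("mat1", label="mat1_int", value=28.0)
    t.mean("d_voc", label="alpha_voc")
    t.mean("d_mat", label="alpha_mat")
    return t


def build_g_model(invariance: str = "weak", age_variant: str = "g_only") -> ParameterTable:
    """Common-factor (g) model with a latent change factor on g.

    Observed scores at each wave load on a wave-specific g factor (voc
    loading fixed to 1 for scale; the mat loading free).  Change happens at
    the factor level: g2 = 1*g1 + 1*dg with self-feedback beta_g.  Same-
    indicator residuals covary across waves.

    ``invariance`` levels:

    * ``"configural"`` — mat loadings free at each wave (18 free, df = 2);
    * ``"weak"`` — mat loadings equated across waves (17 free, df = 3), the
      reference build;
    * ``"strong"`` — loadings and intercepts equated, dg mean freed
      (16 free, df = 4).

    ``age_variant`` places the age covariate: ``"g_only"`` (default) on the
    wave-1 factor; ``"alternative_a"`` on the observed wave-1 scores only;
    ``"alternative_b"`` on both the observed scores and the factor.
    """
    if invariance not in ("configural", "weak", "strong"):
        raise ModelSpecError(f"unknown invariance level {invariance!r}")
    if age_variant not in ("g_only", "alternative_a", "alternative_b"):
        raise ModelSpecError(f"unknown age variant {age_variant!r}")
    v = VariableSet(
        ("age", "voc1", "mat1", "voc2", "mat2", "g1", "g2", "d_g"),
        latent={"g1", "g2", "d_g"},
    )
    t = ParameterTable(v)
    t.path("g1", "voc1", free=False, value=1.0)
    t.path("g2", "voc2", free=False, value=1.0)
    equate = invariance in ("weak", "strong")
    t.path("g1", "mat1", label="lambda_mat" if equate else "lambda_mat_t1", value=0.4)
    t.path("g2", "mat2", label="lambda_mat" if equate else "lambda_mat_t2", value=0.4)
    t.path("g1", "g2", free=False, value=1.0)
    t.path("d_g", "g2", free=False, value=1.0)
    t.path("g1", "d_g", label="beta_g")
    if age_variant in ("g_only", "alternative_b"):
        t.path("age", "g1", label="g1_on_age")
    if age_variant in ("alternative_a", "alternative_b"):
        t.path("age", "voc1", label="voc1_on_age")
        t.path("age", "mat1", label="mat1_on_age")
    t.cov("age", label="age_var", value=9.0)
    t.cov("g1", label="g1_var", value=15.0)
    t.cov("d_g", label="dg_var", value=3.0)
    for ind in ("voc1", "mat1", "voc2", "mat2"):
        t.cov(ind, label=f"{ind}_resid_var", value=10.0)
    t.cov("voc1", "voc2", label="voc_resid_cov")
    t.cov("mat1", "mat2", label="mat_resid_cov")
    t.mean("age", label="age_mean")
    if invariance == "strong":
        t.mean("voc1", label="voc_int", value=55.0)
        t.mean("voc2", label="voc_int", value=55.0)
        t.mean("mat1", label="mat_int", value=28.0)
        t.mean("mat2", label="mat_int", value=28.0)
        t.mean("d_g", label="alpha_g")
    else:
        t.mean("voc1", label="voc1_int", value=55.0)
        t.mean("voc2", label="voc2_int", value=55.0)
        t.mean("mat1", label="mat1_int", value=28.0)
        t.mean("mat2", label="mat2_int", value=28.0)
    return t


@dataclass(frozen=True)
class TheoryModelConfig:
    """Named configuration dispatching to the concrete builders."""

    theory: str = "mutualism"  # g | investment | mutualism
    invariance: str = "weak"
    age_variant: str = "default"
    age_on_change: bool = False

    def __post_init__(self):
        if self.theory not in ("g", "investment", "mutualism"):
            raise ModelSpecError(f"unknown theory {self.theory!r}")
        g_variants = ("default", "g_only", "alternative_a", "alternative_b")
        biv_variants = ("default", "baseline_observed", "age_squared", "age_squared_null")
        ok = g_variants if self.theory == "g" else biv_variants
        if self.age_variant not in ok:
            raise ModelSpecError(
                f"age variant {self.age_variant!r} not admissible for theory {self.theory!r}"
            )


def build_theory(config: TheoryModelConfig) -> ParameterTable:
    """Build the ParameterTable selected by a :class:`TheoryModelConfig`."""
    if config.theory == "g":
        variant = "g_only" if config.age_variant == "default" else config.age_variant
        return build_g_model(invariance=config.invariance, age_variant=variant)
    couplings = (
        {"voc_to_dmat", "mat_to_dvoc"} if config.theory == "mutualism" else {"mat_to_dvoc"}
    )
    age_squared = {"age_squared": "free", "age_squared_null": "null"}.get(config.age_variant)
    return build_bivariate_lcs(
        couplings, age_on_change=config.age_on_change, age_squared=age_squared
    )


# ---------------------------------------------------------------------------
# multigroup
# ---------------------------------------------------------------------------


@dataclass
class MultigroupSpec:
    """Per-group copies of a spec with shared labels for equated parameters."""

    group_specs: dict[str, ParameterTable]
    equated: tuple[str, ...]

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for spec in self.group_specs.values():
            for label in spec.free_labels:
                seen.setdefault(label)
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.labels)


def apply_multigroup(spec: ParameterTable, groups, equality="all") -> MultigroupSpec:
    """Duplicate a spec across groups with equality constraints by label.

    ``equality`` is either ``"all"`` (every free parameter equated across
    groups — the fully constrained comparison model) or an iterable of
    labels to equate; non-equated labels are suffixed per group, so the
    constrained-versus-free comparison has delta-df equal to the number of
    equated labels times (number of groups - 1).
    """
    groups = list(groups)
    if not groups:
        raise ModelSpecError("empty group list")
    all_labels = spec.free_labels
    equated = tuple(all_labels) if equality == "all" else tuple(equality)
    unknown = set(equated) - set(all_labels)
    if unknown:
        raise ModelSpecError(f"equality labels not in spec: {sorted(unknown)}")
    out = {}
    for g in groups:
        out[str(g)] = spec.relabel(
            lambda label, g=g: label if label in equated else f"{label}@{g}"
        )
    return MultigroupSpec(out, equated)


def fit_multigroup(mspec: MultigroupSpec, data, group_col: str = "sex", options=None):
    """Fit a multigroup spec by summed FIML over the per-group subsets.

    Groups are the distinct values of ``group_col`` in the panel frame and
    must match the spec's group keys.  Age is centered at the pooled sample
    mean so group contrasts stay on one scale.  Returns a
    :class:`~lcspanel.estimation.FitResult` whose labels span all groups.
    """
    import scipy.optimize as _opt

    from .estimation import (
        DataContractError,
        FitOptions,
        FitResult,
        PanelDataset,
        _FimlProblem,
        _inverse_transform,
        _moment_matched_start,
        _OptProblem,
        _polish,
        _transform,
    )

    options = options or FitOptions()
    if not isinstance(data, PanelDataset):
        raise DataContractError("multigroup fitting needs a PanelDataset")
    frame = data.frame
    if group_col not in frame.columns:
        raise DataContractError(f"no grouping column {group_col!r}")
    values = [str(v) for v in frame[group_col].dropna().unique()]
    if set(values) != set(mspec.group_specs):
        raise DataContractError(
            f"data groups {sorted(values)} do not match spec groups "
            f"{sorted(mspec.group_specs)}"
        )

    age_mean = data.age_mean()
    global_labels = mspec.labels
    pos = {l: i for i, l in enumerate(global_labels)}
    parts = []  # (problem, global index array)
    start = np.zeros(len(global_labels))
    is_variance = np.zeros(len(global_labels), dtype=bool)
    for g, spec in mspec.group_specs.items():
        sub = frame[frame[group_col].astype(str) == g].copy()
        sub["age_t1"] = sub["age_t1"] - age_mean
        Y = PanelDataset(sub).matrix(spec.variables.observed, center_age=False)
        compiled = spec.compile()
        idx = np.array([pos[l] for l in compiled.labels])
        parts.append((_FimlProblem(compiled, Y), idx))
        start[idx] = _moment_matched_start(spec, Y)
        is_variance[idx] = compiled.is_variance

    class _Joint:
        def value_and_grad(self, theta):
            ll = 0.0
            grad = np.zeros(len(global_labels))
            for problem, idx in parts:
                l, g_ = problem.value_and_grad(theta[idx])
                if not np.isfinite(l):
                    return -np.inf, grad * 0
                ll += l
                np.add.at(grad, idx, g_)
            return ll, grad

    joint = _Joint()
    obj = _OptProblem.__new__(_OptProblem)
    obj.p = joint
    obj.is_variance = is_variance

    x0 = _inverse_transform(start, is_variance)
    rng = np.random.default_rng(options.seed)
    best = None
    for s in range(max(options.n_starts, 1)):
        xs = x0 if s == 0 else x0 + rng.normal(0.0, options.jitter, x0.size)
        res = _opt.minimize(
            obj, xs, jac=True, method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": options.ftol * 1e-2,
                     "gtol": options.gtol * 1e-2, "maxcor": 20},
        )
        if best is None or res.fun < best.fun:
            best = res
    x, f, gr = _polish(obj, best.x, options)
    theta = _transform(x, is_variance)
    grad_norm = float(np.max(np.abs(gr)))
    first_spec = next(iter(mspec.group_specs.values()))
    return FitResult(
        spec=first_spec,
        labels=list(global_labels),
        theta=theta,
        loglik=-f,
        converged=bool(np.isfinite(f) and grad_norm < options.gtol),
        grad_norm=grad_norm,
        n_subjects=len(frame),
        center_age=False,
    )


# ---------------------------------------------------------------------------
# interval rescaling
# ---------------------------------------------------------------------------


def rescale_time2(y1, y2, interval, reference_interval: float = REFERENCE_INTERVAL):
    """Annualize wave-2 scores to a common inter-test interval.

    Linear rescaling of the observed change to the reference interval:
    ``y2' = y1 + (y2 - y1) * reference_interval / interval``.  Missing wave-2
    values stay missing; non-positive intervals (where y2 is present) raise.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    interval = np.asarray(interval, dtype=float)
    present = ~np.isnan(y2)
    if np.any(present & ~(interval > 0)):
        raise ValueError("non-positive inter-test interval with a wave-2 score present")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = y1 + (y2 - y1) * (reference_interval / interval)
    return np.where(present, out, np.nan)


def rescale_dataset(data, reference_interval: float = REFERENCE_INTERVAL):
    """Copy of a panel dataset with both wave-2 scores annualized."""
    from .estimation import PanelDataset

    frame = data.frame.copy()
    for col1, col2 in (("voc_t1", "voc_t2"), ("mat_t1", "mat_t2")):
        frame[col2] = rescale_time2(
            frame[col1].to_numpy(float),
            frame[col2].to_numpy(float),
            frame["interval"].to_numpy(float),
            reference_interval,
        )
    return PanelDataset(frame)
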