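"""Model-implied dynamics and the end-to-end theory-comparison pipeline.

Once a bivariate latent-change model is fitted, its change equations

    E[d voc] = alpha_voc + beta_voc * voc1 + gamma_mat_to_dvoc * mat1
    E[d mat] = alpha_mat + beta_mat * mat1 + gamma_voc_to_dmat * voc1

can be evaluated on a grid of hypothetical wave-1 states to draw a vector
field of expected development (arrows from wave-1 to expected wave-2
position), and the implied change-factor variances decompose into the share
explained by the self-feedback/coupling structure versus residual change.

:func:`run_comparison` wires the whole analysis together: saturated and
baseline reference fits, the three theory models, fit indices, Akaike
weights, the nested mutualism-versus-investment test, the measurement-
invariance sequence for the factor family, and the vector field of the
winning bivariate model.  All outputs are plain CSV/key-value text and the
run is byte-deterministic given its options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import (
    FitOptions,
    FitResult,
    PanelDataset,
    baseline_fit,
    fit_model,
    observed_information_se,
    saturated_fit,
)
from .fit_compare import (
    ComparisonTable,
    akaike_weights,
    compare_models,
    invariance_sequence,
    lr_test,
)
from .model_core import assemble
from .theory_models import TheoryModelConfig, build_theory, rescale_dataset

__all__ = [
    "VectorField",
    "expected_change_field",
    "variance_explained",
    "CompareOptions",
    "ComparisonResult",
    "run_comparison",
]


@dataclass
class VectorField:
    """Expected-change arrows on a rectangular grid of wave-1 scores.

    ``dvoc[i, j]`` and ``dmat[i, j]`` are the expected changes at
    ``(voc_grid[i], mat_grid[j])``; each arrow is the exact change-equation
    evaluation at that point (no smoothing or interpolation).
    """

    voc_grid: np.ndarray
    mat_grid: np.ndarray
    dvoc: np.ndarray
    dmat: np.ndarray
    age: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        V, M = np.meshgrid(self.voc_grid, self.mat_grid, indexing="ij")
        return pd.DataFrame(
            {
                "voc1": V.ravel(),
                "mat1": M.ravel(),
                "expected_dvoc": self.dvoc.ravel(),
                "expected_dmat": self.dmat.ravel(),
            }
        )

    def plot(self, ax=None, **quiver_kw):
        """Quiver plot of the field (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        V, M = np.meshgrid(self.voc_grid, self.mat_grid, indexing="ij")
        quiver_kw.setdefault("angles", "xy")
        quiver_kw.setdefault("scale_units", "xy")
        quiver_kw.setdefault("scale", 1.0)
        ax.quiver(V, M, self.dvoc, self.dmat, **quiver_kw)
        ax.set_xlabel("Vocabulary (wave 1)")
        ax.set_ylabel("Matrix Reasoning (wave 1)")
        return ax


def expected_change_field(
    fit: FitResult,
    voc_grid,
    mat_grid,
    age_centered: float = 0.0,
) -> VectorField:
    """Evaluate a fitted bivariate model's change equations on a grid.

    ``age_centered`` is the conditioning age relative to the sample mean
    (0 = the mean-aged subject); it only matters for the age-on-change
    model variant, since in the reference models age affects wave-1 levels
    but not the change equations, so arrows are functions of the plotted
    wave-1 scores alone.
    """
    voc_grid = np.asarray(voc_grid, dtype=float)
    mat_grid = np.asarray(mat_grid, dtype=float)
    for g in (voc_grid, mat_grid):
        if g.ndim != 1 or np.any(np.diff(g) <= 0) or not np.all(np.isfinite(g)):
            raise ValueError("grids must be 1-D, finite and strictly increasing")
    est = fit.estimates()
    needed = {"alpha_voc", "alpha_mat", "beta_voc", "beta_mat"}
    if not needed <= est.keys():
        raise ValueError("not a bivariate latent-change fit")
    V, M = np.meshgrid(voc_grid, mat_grid, indexing="ij")
    dvoc = (
        est["alpha_voc"]
        + est["beta_voc"] * V
        + est.get("gamma_mat_to_dvoc", 0.0) * M
        + est.get("dvoc_on_age", 0.0) * age_centered
    )
    dmat = (
        est["alpha_mat"]
        + est["beta_mat"] * M
        + est.get("gamma_voc_to_dmat", 0.0) * V
        + est.get("dmat_on_age", 0.0) * age_centered
    )
    return VectorField(voc_grid, mat_grid, dvoc, dmat, age=age_centered)


def variance_explained(fit: FitResult) -> dict[str, float]:
    """Share of change-score variance explained by the structural paths.

    For each change factor: 1 - (residual change variance) / (total implied
    change variance), both taken from the implied moments over the full
    variable set (latents included).  Invariant to consistent linear
    rescaling of the observed scores.
    """
    ram = assemble(fit.spec, fit.theta)
    _, sigma_full = ram.full_moments()
    names = list(ram.names)
    out = {}
    for domain, latent in (("voc", "d_voc"), ("mat", "d_mat")):
        if latent not in names:
            raise ValueError("not a bivariate latent-change fit")
        i = names.index(latent)
        total = sigma_full[i, i]
        if total <= 0:
            raise ValueError(f"zero total change variance for {latent}")
        resid = fit.estimate(f"d{domain}_var")
        out[domain] = float(min(max(1.0 - resid / total, 0.0), 1.0))
    return out


@dataclass
class CompareOptions:
    """Options for :func:`run_comparison`."""

    seed: int = 0
    fit: FitOptions = field(default_factory=FitOptions)
    rescale_intervals: bool = False
    standard_errors: bool = True
    vector_field: bool = True
    grid_points: int = 9
    invariance: bool = True
    out_dir: str | Path | None = None


@dataclass
class ComparisonResult:
    """Everything the three-theory comparison pipeline produces."""

    fits: dict[str, FitResult]
    saturated: object
    baseline: object
    table: ComparisonTable
    indices: pd.DataFrame
    lrt: tuple
    invariance: pd.DataFrame | None
    field: VectorField | None
    variance_explained: dict | None
    manifest: dict


def run_comparison(data: PanelDataset, options: CompareOptions | None = None) -> ComparisonResult:
    """Fit and compare the g-factor, investment and mutualism models.

    Fits the saturated and independence reference models, the three theory
    models, computes fit indices and Akaike weights, runs the nested
    likelihood-ratio test of investment within mutualism and the
    longitudinal invariance sequence for the factor family, and evaluates
    the expected-change vector field of the best bivariate model.  When
    ``out_dir`` is set, writes the comparison, fit-index, per-model
    parameter and vector-field CSVs plus a key-value run manifest; rerunning
    with identical inputs and options reproduces the files byte for byte.
    """
    options = options or CompareOptions()
    if options.rescale_intervals:
        data = rescale_dataset(data)
    opts = options.fit

    sat = saturated_fit(data)
    base = baseline_fit(data)
    names = ("g", "investment", "mutualism")
    fits: dict[str, FitResult] = {}
    for name in names:
        spec = build_theory(TheoryModelConfig(theory=name))
        fits[name] = fit_model(spec, data, opts)
        if options.standard_errors:
            observed_information_se(fits[name], data)
    table, indices = compare_models(fits, sat, base)
    lrt = lr_test(fits["mutualism"], fits["investment"])
    inv = invariance_sequence(data, options=opts) if options.invariance else None

    field = None
    varexp = None
    best_bivariate = next(m for m in table.frame["model"] if m != "g")
    winner = fits[best_bivariate]
    varexp = variance_explained(winner)
    if options.vector_field:
        f = data.frame
        voc_grid = np.linspace(f["voc_t1"].quantile(0.05), f["voc_t1"].quantile(0.95),
                               options.grid_points)
        mat_grid = np.linspace(f["mat_t1"].quantile(0.05), f["mat_t1"].quantile(0.95),
                               options.grid_points)
        field = expected_change_field(winner, voc_grid, mat_grid)

    manifest = {
        "n_subjects": data.n,
        "seed": opts.seed,
        "n_starts": opts.n_starts,
        "gtol": opts.gtol,
        "rescale_intervals": options.rescale_intervals,
        "best_model": table.best,
        "lrt_delta_T": round(lrt.delta_T, 10),
        "lrt_delta_df": lrt.delta_df,
    }
    for name in names:
        manifest[f"converged_{name}"] = fits[name].converged
        manifest[f"loglik_{name}"] = round(fits[name].loglik, 10)

    result = ComparisonResult(
        fits=fits,
        saturated=sat,
        baseline=base,
        table=table,
        indices=indices,
        lrt=lrt,
        invariance=inv,
        field=field,
        variance_explained=varexp,
        manifest=manifest,
    )
    if options.out_dir is not None:
        _write_outputs(result, Path(options.out_dir))
    return result


def _write_outputs(result: ComparisonResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "comparison.csv")
    result.indices.to_csv(out_dir / "fit_indices.csv", index=False)
    for name, fit in result.fits.items():
        fit.to_csv(out_dir / f"params_{name}.csv")
    if result.invariance is not None:
        result.invariance.to_csv(out_dir / "invariance.csv", index=False)
    if result.field is not None:
        result.field.to_frame().to_csv(out_dir / "vector_field.csv", index=False)
    with open(out_dir / "manifest.txt", "w") as fh:
        for key in sorted(result.manifest):
            fh.write(f"{key}\t{result.manifest[key]}\n")
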