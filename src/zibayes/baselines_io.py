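"""Logistic-regression comparators and dataset I/O.

The pooled logistic fit is the conventional analysis that ignores the
at-risk distinction: because the marginal outcome is Bernoulli(omega*p),
its intercept-only fitted probability estimates the *product* omega*p,
never the two factors — the comparison that motivates the ZIB model.
The exposed-only fit conditions on the latent at-risk labels (available
in simulations, rarely in practice) and estimates the occurrence part
alone.

Maximum-likelihood fitting goes through statsmodels (IRLS); the
intercept-only model additionally reports the closed-form proportion
m/n with its Wald interval on the probability scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .zib_core import BinaryOutcomeData

__all__ = ["LogisticFit", "fit_logistic", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class LogisticFit:
    """Logistic MLE with Wald 95% intervals on the coefficient scale.

    For intercept-only models, ``proportion`` and ``proportion_ci`` carry
    the closed-form sample proportion m/n and its probability-scale Wald
    interval m/n +- 1.96 sqrt(m/n (1 - m/n) / n).
    """

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    n: int
    proportion: float | None = None
    proportion_ci: tuple[float, float] | None = None
    warnings: list[str] = field(default_factory=list)


def fit_logistic(
    data: BinaryOutcomeData,
    covariates: str = "none",
    population: str = "all",
) -> LogisticFit:
    """Fit a plain logistic regression comparator.

    ``covariates`` selects the design block: "none" (intercept only),
    "structural" (the X block) or "occurrence" (the Z block).
    ``population`` is "all" (pooled) or "exposed" (requires latent
    exposure labels, as in simulated data).
    """
    if population == "exposed":
        if data.exposure is None:
            raise ValueError(
                "exposed-only fit requires latent exposure labels on the data"
            )
        keep = np.asarray(data.exposure) == 1
    elif population == "all":
        keep = np.ones(data.n, bool)
    else:
        raise ValueError(f"population must be 'all' or 'exposed', got {population!r}")

    y = data.y[keep]
    if covariates == "none":
        block = np.empty((keep.sum(), 0))
        names = ["intercept"]
    elif covariates == "structural":
        block = data.X[keep]
        names = ["intercept"] + [f"x{j + 1}" for j in range(block.shape[1])]
    elif covariates == "occurrence":
        block = data.Z[keep]
        names = ["intercept"] + [f"z{j + 1}" for j in range(block.shape[1])]
    else:
        raise ValueError(f"unknown covariate selector {covariates!r}")

    design = np.hstack([np.ones((y.shape[0], 1)), block])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")

    warnings: list[str] = []
    res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
    if not res.converged or np.abs(res.params).max() > 20:
        msg = "possible separation: coefficients diverging, iterations capped"
        warnings.append(msg)
        logger.warning(msg)

    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    ci = pd.DataFrame(
        np.column_stack([res.params - _Z975 * res.bse, res.params + _Z975 * res.bse]),
        index=names,
        columns=["lower", "upper"],
    )

    proportion = proportion_ci = None
    if covariates == "none":
        n = int(y.shape[0])
        prop = float(y.mean())
        half = _Z975 * np.sqrt(prop * (1.0 - prop) / n)
        proportion, proportion_ci = prop, (prop - half, prop + half)

    return LogisticFit(
        params=params,
        bse=bse,
        conf_int=ci,
        n=int(y.shape[0]),
        proportion=proportion,
        proportion_ci=proportion_ci,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def _encode(frame: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Reference-code categorical columns (first level = reference)."""
    manifest: dict = {}
    blocks: list[np.ndarray] = []
    for col in frame.columns:
        s = frame[col]
        if s.dtype.kind in "biufc":
            blocks.append(s.to_numpy(float)[:, None])
            manifest[col] = {"kind": "numeric"}
        else:
            levels = list(pd.unique(s.astype(str)))
            ref, others = levels[0], levels[1:]
            for lev in others:
                blocks.append((s.astype(str) == lev).to_numpy(float)[:, None])
            manifest[col] = {"kind": "categorical", "reference": ref, "levels": levels}
    mat = np.hstack(blocks) if blocks else np.empty((len(frame), 0))
    return mat, manifest


def read_dataset(
    path: str | Path,
    outcome: str,
    structural_cols: list[str] | None = None,
    occurrence_cols: list[str] | None = None,
) -> tuple[BinaryOutcomeData, dict]:
    """Read a CSV with header into :class:`BinaryOutcomeData`.

    Categorical covariates are expanded to reference-coded indicators;
    rows with missing values in any used column are dropped with a
    logged count.  Returns the data and a column-coding manifest.
    """
    structural_cols = structural_cols or []
    occurrence_cols = occurrence_cols or []
    frame = pd.read_csv(path)
    used = [outcome] + structural_cols + occurrence_cols
    for col in used:
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    frame = frame[used]
    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        logger.warning("dropped %d rows with missing values", dropped)

    y_raw = frame[outcome]
    y = pd.to_numeric(y_raw, errors="coerce")
    if y.isna().any() or not y.isin((0, 1)).all():
        raise ValueError(f"outcome column {outcome!r} is not coercible to 0/1")

    X, man_x = _encode(frame[structural_cols])
    Z, man_z = _encode(frame[occurrence_cols])
    manifest = {
        "outcome": outcome,
        "structural": man_x,
        "occurrence": man_z,
        "rows_dropped": dropped,
    }
    return BinaryOutcomeData(y=y.to_numpy(int), X=X, Z=Z), manifest


def write_dataset(
    data: BinaryOutcomeData, path: str | Path, with_latent: bool = False
) -> None:
    """Write a dataset as CSV: y, x1..xk, z1..zm (+ exposure if requested)."""
    cols = {"y": data.y}
    for j in range(data.X.shape[1]):
        cols[f"x{j + 1}"] = data.X[:, j]
    for j in range(data.Z.shape[1]):
        cols[f"z{j + 1}"] = data.Z[:, j]
    if with_latent and data.exposure is not None:
        cols["exposure"] = data.exposure
    pd.DataFrame(cols).to_csv(path, index=False)
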