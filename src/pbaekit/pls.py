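"""NIPALS partial least squares regression for polymer chemometrics.

Links a standardized polymer descriptor matrix X (n polymers × p descriptors)
to one or two uptake-ratio responses Y.  Components are extracted one at a
time by the NIPALS iteration with deflation of both blocks, which handles the
strong multicollinearity of monomer/repeat-unit property tables that defeats
ordinary least squares.

Variance bookkeeping follows the deflation: per-component X-R² and Y-R² are
Frobenius-norm shares of the initial autoscaled matrices, so the per-component
columns sum exactly to the cumulative columns.  Component count is chosen from
the RMSE scree curve (inflection = maximal discrete second difference), with
the ≥80%-of-X-variance criterion reported alongside.

The number of components H is capped at min(n−1, p); at that cap on full-rank
data the PLS predictions coincide with OLS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "ScreeCurve",
    "ComponentSelection",
    "fit_pls",
    "predict",
    "rmse_scree",
    "loo_rmse_scree",
    "select_components",
    "variance_tables",
    "loading_map",
    "variable_response_correlations",
]


@dataclass
class PLSModel:
    """Fitted NIPALS PLS model (weights, loadings, scores, R² bookkeeping)."""

    x_means: np.ndarray
    x_sds: np.ndarray
    y_means: np.ndarray
    y_sds: np.ndarray
    W: np.ndarray  # x-weights, (p, H), unit-norm columns
    P: np.ndarray  # x-loadings, (p, H)
    Q: np.ndarray  # y-loadings, (q, H)
    T: np.ndarray  # scores, (n, H)
    r2x_per_component: np.ndarray
    r2x_cumulative: np.ndarray
    r2y_per_component: np.ndarray
    r2y_cumulative: np.ndarray
    H: int
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)
    X0: np.ndarray | None = None  # training X, autoscaled (pre-deflation)
    Y0: np.ndarray | None = None  # training Y, autoscaled

    def coefficients(self, h: int) -> np.ndarray:
        """Regression matrix B (p × q) on the autoscaled scale, h components."""
        if not 0 <= h <= self.H:
            raise ValueError(f"h must be in [0, {self.H}]")
        if h == 0:
            return np.zeros((self.W.shape[0], self.Q.shape[0]))
        W, P, Q = self.W[:, :h], self.P[:, :h], self.Q[:, :h]
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def to_json(self) -> str:
        doc = {
            "H": self.H,
            "x_names": self.x_names,
            "y_names": self.y_names,
            **{
                k: getattr(self, k).tolist()
                for k in (
                    "x_means", "x_sds", "y_means", "y_sds", "W", "P", "Q", "T",
                    "r2x_per_component", "r2x_cumulative",
                    "r2y_per_component", "r2y_cumulative",
                )
            },
        }
        return json.dumps(doc, indent=1)


@dataclass
class ScreeCurve:
    """In-sample RMSE (standardized response units) at h = 1..H components."""

    h: np.ndarray
    rmse: np.ndarray


@dataclass
class ComponentSelection:
    """Chosen component count with all selection criteria reported."""

    h_selected: int
    h_elbow: int          # RMSE-curve second-difference elbow
    h_inflection_x: int   # inflection of the cumulative X-R² curve
    h_variance: int | None
    threshold: float
    rationale: str


def _autoscale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0)
        raise ValueError(f"zero-variance column(s) at indices {bad.tolist()}")
    return (M - means) / sds, means, sds


def _as_matrix(A) -> tuple[np.ndarray, list[str]]:
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(dtype=float), [str(c) for c in A.columns]
    M = np.asarray(A, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M, [f"var_{j}" for j in range(M.shape[1])]


def fit_pls(
    X,
    Y,
    H: int,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> PLSModel:
    """Fit a NIPALS PLS2 (or PLS1) model with H components.

    Both blocks are autoscaled (zero mean, unit sample SD per column).  Each
    component iterates u → w = Xᵀu/‖Xᵀu‖ → t = Xw → q = Yᵀt/tᵀt → u = Yq/qᵀq
    until the weight vector change drops below ``tol``, then deflates X and Y
    by the score t.  For a single response the iteration converges in one
    pass (w ∝ Xᵀy).  Sign convention: the largest-magnitude element of each
    weight vector is positive.

    If the X residual is numerically exhausted before H components, the model
    is truncated with a warning.
    """
    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    n, p = Xm.shape
    if Ym.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not 1 <= H <= min(n - 1, p):
        raise ValueError(f"H must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(Ym))):
        raise ValueError("X/Y contain non-finite values")

    X0, x_means, x_sds = _autoscale(Xm)
    Y0, y_means, y_sds = _autoscale(Ym)
    ssx0 = np.sum(X0 * X0)
    ssy0 = np.sum(Y0 * Y0)

    Xr, Yr = X0.copy(), Y0.copy()
    q = Y0.shape[1]
    Ws, Ps, Qs, Ts = [], [], [], []
    r2x, r2y = [], []
    fitted_H = H
    for h in range(H):
        ssx_res = np.sum(Xr * Xr)
        if ssx_res < 1e-12 * max(ssx0, 1.0):
            warnings.warn(
                f"X variance exhausted after {h} components; truncating H",
                stacklevel=2,
            )
            fitted_H = h
            break
        # start u: response column with the largest residual variance
        u = Yr[:, np.argmax(np.sum(Yr * Yr, axis=0))].copy()
        if not np.any(u):
            u = Xr[:, int(np.argmax(np.sum(Xr * Xr, axis=0)))].copy()
        w_old = None
        for _ in range(max_iter):
            w = Xr.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"degenerate weight vector at component {h + 1}")
            w /= norm
            t = Xr @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"zero score vector at component {h + 1}")
            qv = Yr.T @ t / tt
            if w_old is not None:
                # sign-aligned change: the weight direction is defined up to
                # sign until the post-hoc convention is applied
                d = min(np.linalg.norm(w - w_old), np.linalg.norm(w + w_old))
                if d < tol:
                    break
            if q == 1:
                break  # single response: closed form, converged
            qq = qv @ qv
            u = Yr @ qv / qq if qq > 0 else t.copy()
            w_old = w
        else:
            raise RuntimeError(
                f"NIPALS failed to converge at component {h + 1} "
                f"(tol={tol}, max_iter={max_iter})"
            )
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, qv = -w, -t, -qv
        tt = t @ t
        pv = Xr.T @ t / tt
        Xr = Xr - np.outer(t, pv)
        Yr = Yr - np.outer(t, qv)
        Ws.append(w)
        Ps.append(pv)
        Qs.append(qv)
        Ts.append(t)
        r2x.append(tt * (pv @ pv) / ssx0)
        r2y.append(tt * (qv @ qv) / ssy0)

    if fitted_H == 0:
        raise ValueError("no PLS components could be extracted")
    W = np.column_stack(Ws)
    return PLSModel(
        x_means=x_means, x_sds=x_sds, y_means=y_means, y_sds=y_sds,
        W=W, P=np.column_stack(Ps), Q=np.column_stack(Qs), T=np.column_stack(Ts),
        r2x_per_component=np.array(r2x),
        r2x_cumulative=np.cumsum(r2x),
        r2y_per_component=np.array(r2y),
        r2y_cumulative=np.cumsum(r2y),
        H=fitted_H, x_names=x_names, y_names=y_names, X0=X0, Y0=Y0,
    )


def predict(model: PLSModel, X_new, h: int | None = None) -> np.ndarray:
    """Predict responses in original units using h components.

    ``h = 0`` predicts the training response means.  X_new must carry the
    training descriptor columns (name-checked when a DataFrame is given).
    """
    if h is None:
        h = model.H
    Xm, names = _as_matrix(X_new)
    if isinstance(X_new, pd.DataFrame) and model.x_names and names != model.x_names:
        raise ValueError("descriptor columns do not match the training table")
    if Xm.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"expected {model.W.shape[0]} descriptor columns, got {Xm.shape[1]}"
        )
    X0 = (Xm - model.x_means) / model.x_sds
    Y0_hat = X0 @ model.coefficients(h)
    return Y0_hat * model.y_sds + model.y_means


def rmse_scree(model: PLSModel) -> ScreeCurve:
    """In-sample RMSE over all n×q standardized residuals at h = 1..H."""
    if model.X0 is None or model.Y0 is None:
        raise ValueError("model was fitted without stored training blocks")
    rmse = []
    for h in range(1, model.H + 1):
        R = model.Y0 - model.X0 @ model.coefficients(h)
        rmse.append(float(np.sqrt(np.mean(R * R))))
    return ScreeCurve(h=np.arange(1, model.H + 1), rmse=np.array(rmse))


def loo_rmse_scree(X, Y, H: int) -> ScreeCurve:
    """Leave-one-out cross-validated RMSE curve (optional alternative scree)."""
    Xm, _ = _as_matrix(X)
    Ym, _ = _as_matrix(Y)
    n = Xm.shape[0]
    sse = np.zeros(H)
    y_sds_full = Ym.std(axis=0, ddof=1)
    for i in range(n):
        mask = np.arange(n) != i
        m = fit_pls(Xm[mask], Ym[mask], H)
        for h in range(1, m.H + 1):
            r = (predict(m, Xm[i : i + 1], h) - Ym[i : i + 1]) / y_sds_full
            sse[h - 1] += float(np.sum(r * r))
        for h in range(m.H + 1, H + 1):  # truncated fits reuse deepest model
            r = (predict(m, Xm[i : i + 1], m.H) - Ym[i : i + 1]) / y_sds_full
            sse[h - 1] += float(np.sum(r * r))
    q = Ym.shape[1] if Ym.ndim > 1 else 1
    return ScreeCurve(h=np.arange(1, H + 1), rmse=np.sqrt(sse / (n * q)))


def select_components(
    scree: ScreeCurve,
    r2x_cumulative: np.ndarray,
    threshold: float = 0.80,
    criterion: str = "x_inflection",
) -> ComponentSelection:
    """Choose the component count from the scree/variance inflection.

    Three diagnostics are computed and reported:

    * ``h_elbow`` — discrete second difference of the RMSE curve,
      rmse[h−1] − 2·rmse[h] + rmse[h+1], maximised over interior components
      2..H−1 (the sharpest bend of the prediction-error curve);
    * ``h_inflection_x`` — the inflection of the cumulative X-R² curve: the
      component maximising the vertical distance between the curve and its
      end-to-end chord (where explained descriptor variance stops growing);
    * ``h_variance`` — the smallest h whose cumulative X-R² reaches
      ``threshold`` (default 80% of input variance).

    ``criterion`` picks ``h_selected``: ``"x_inflection"`` (default) or
    ``"rmse_elbow"``.  With two responses the prediction-error curve flattens
    once the rank-q response space is spanned (after ≤2 components), so it
    cannot reflect a higher latent dimension of the descriptors; the X-R²
    inflection does, which is why it is the default.  A warning is logged
    when the selected h explains less X variance than ``threshold``.
    """
    rmse = np.asarray(scree.rmse, dtype=float)
    r2x = np.asarray(r2x_cumulative, dtype=float)
    Hn = rmse.size
    if Hn < 3:
        raise ValueError("need H >= 3 for an interior scree inflection")
    second_diff = rmse[:-2] - 2 * rmse[1:-1] + rmse[2:]  # at h = 2..H-1
    h_elbow = int(np.argmax(second_diff)) + 2
    h = np.arange(1, r2x.size + 1)
    chord = r2x[0] + (r2x[-1] - r2x[0]) * (h - 1) / (r2x.size - 1)
    h_inflection_x = int(np.argmax(r2x - chord)) + 1
    reaching = np.flatnonzero(r2x >= threshold)
    h_variance = int(reaching[0]) + 1 if reaching.size else None
    if criterion == "x_inflection":
        h_selected = h_inflection_x
    elif criterion == "rmse_elbow":
        h_selected = h_elbow
    else:
        raise ValueError("criterion must be 'x_inflection' or 'rmse_elbow'")
    rationale = (
        f"X-R2 inflection at h={h_inflection_x}; RMSE elbow at h={h_elbow}; "
        f"cumulative X-R2 reaches {threshold:.0%} at "
        f"h={h_variance if h_variance is not None else '>H'}; "
        f"selected by {criterion}"
    )
    if h_selected <= len(r2x) and r2x[h_selected - 1] < threshold:
        warnings.warn(
            f"selected h={h_selected} explains {r2x[h_selected - 1]:.2f} of X "
            f"variance, below the {threshold:.0%} criterion",
            stacklevel=2,
        )
    return ComponentSelection(
        h_selected=h_selected, h_elbow=h_elbow, h_inflection_x=h_inflection_x,
        h_variance=h_variance, threshold=threshold, rationale=rationale,
    )


def variance_tables(model: PLSModel) -> pd.DataFrame:
    """Per-component and cumulative X/Y R² table over h = 1..H."""
    return pd.DataFrame(
        {
            "n_components": np.arange(1, model.H + 1),
            "X_R2": model.r2x_per_component,
            "X_R2_cum": model.r2x_cumulative,
            "Y_R2": model.r2y_per_component,
            "Y_R2_cum": model.r2y_cumulative,
        }
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def loading_map(model: PLSModel) -> pd.DataFrame:
    """Circle-of-correlations coordinates on components 1–2.

    Each descriptor (and each response) is placed at its Pearson correlation
    with the first two score vectors, so all coordinates lie in [−1, 1] and
    co-located variables are closely related.
    """
    if model.H < 2:
        raise ValueError("need at least 2 fitted components for a loading map")
    t1, t2 = model.T[:, 0], model.T[:, 1]
    rows = []
    for j, name in enumerate(model.x_names):
        col = model.X0[:, j]
        rows.append((name, "descriptor", _safe_corr(col, t1), _safe_corr(col, t2)))
    for k, name in enumerate(model.y_names):
        col = model.Y0[:, k]
        rows.append((name, "response", _safe_corr(col, t1), _safe_corr(col, t2)))
    return pd.DataFrame(rows, columns=["name", "kind", "comp1", "comp2"])


def variable_response_correlations(
    model: PLSModel, h: int | None = None, against: str = "prediction"
) -> pd.DataFrame:
    """Signed per-descriptor importance profile for each response.

    For descriptor j and response k: the Pearson correlation between the
    standardized descriptor column and the h-component model prediction of
    that response (``against="observed"`` correlates with the observed
    response instead).  Constant predictions yield correlation 0 with a
    ``degenerate`` flag.
    """
    if h is None:
        h = model.H
    if not 1 <= h <= model.H:
        raise ValueError(f"h must be in [1, {model.H}]")
    if against not in ("prediction", "observed"):
        raise ValueError("against must be 'prediction' or 'observed'")
    target = model.X0 @ model.coefficients(h) if against == "prediction" else model.Y0
    rows = []
    for k, yname in enumerate(model.y_names):
        col = target[:, k]
        degenerate = col.std() == 0
        for j, xname in enumerate(model.x_names):
            r = 0.0 if degenerate else _safe_corr(model.X0[:, j], col)
            rows.append((xname, yname, r, degenerate))
    return pd.DataFrame(
        rows, columns=["descriptor", "response", "correlation", "degenerate"]
    )
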