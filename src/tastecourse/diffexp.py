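"""Negative-binomial GLM likelihood-ratio tests across growth stages.

Each gene's counts over (7 stages) x (2 replicates) are modelled with a
log-link negative-binomial GLM, variance = mu + phi * mu^2 (phi = 0 degrades
to Poisson).  The full model is ``~ stage + replicate``; the reduced model
``~ replicate``; the ANOVA-like likelihood-ratio statistic
2 * (l_full - l_reduced) is referred to a chi-square with
(n_stages - 1) degrees of freedom.  Library sizes enter as log offsets.

Fitting is iteratively reweighted least squares, vectorized across genes
(all genes share the design matrix, so each IRLS step is a batch of small
weighted least-squares solves).  Dispersion is estimated by Cox-Reid
adjusted profile likelihood (beta re-fitted at every candidate phi), either
genewise, as one common value, or genewise shrunk toward the common
likelihood curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .containers import StageMatrix
from .errors import InputError

logger = logging.getLogger(__name__)

_PHI_POISSON = 1e-10  # below this, treat the model as Poisson
_MU_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Stage + replicate design over the stacked (A then B) observations."""

    stages: list[str]
    X_full: np.ndarray
    X_reduced: np.ndarray
    offsets: np.ndarray

    @property
    def df_test(self) -> int:
        return self.X_full.shape[1] - self.X_reduced.shape[1]

    @property
    def residual_df(self) -> int:
        return self.X_full.shape[0] - self.X_full.shape[1]


def build_design(stages, mapped_totals_a, mapped_totals_b) -> DesignSpec:
    """Full (intercept + stage + replicate) and reduced (intercept + replicate)
    design matrices, with log library-size offsets."""
    ns = len(stages)
    n = 2 * ns
    X_full = np.zeros((n, ns + 1))
    X_full[:, 0] = 1.0
    for j in range(1, ns):  # stage dummies relative to the first day
        X_full[j, j] = 1.0
        X_full[ns + j, j] = 1.0
    X_full[ns:, ns] = 1.0  # replicate B indicator
    X_reduced = X_full[:, [0, ns]].copy()
    offsets = np.log(np.concatenate([
        np.asarray(mapped_totals_a, dtype=float),
        np.asarray(mapped_totals_b, dtype=float),
    ]))
    return DesignSpec(stages=list(stages), X_full=X_full,
                      X_reduced=X_reduced, offsets=offsets)


# ---------------------------------------------------------------------------
# likelihood / deviance
# ---------------------------------------------------------------------------

def _as_phi_col(phi, n_genes: int) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(n_genes, float(phi))
    if phi.shape != (n_genes,):
        raise InputError("dispersion must be scalar or one value per gene")
    if (phi < 0).any():
        raise InputError("dispersion must be >= 0")
    return phi[:, None]


def nb_loglik(Y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Exact per-gene NB (or Poisson when phi=0) log-likelihood."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mu = np.maximum(np.atleast_2d(mu), _MU_FLOOR)
    phi_col = _as_phi_col(phi, Y.shape[0])
    pois = Y * np.log(mu) - mu - gammaln(Y + 1.0)
    r = 1.0 / np.maximum(phi_col, _PHI_POISSON)
    nb = (gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
          + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu)))
    out = np.where(phi_col < _PHI_POISSON, pois, nb)
    return out.sum(axis=1)


def _deviance(Y: np.ndarray, mu: np.ndarray, phi_col: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, _MU_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(Y > 0, Y * np.log(np.maximum(Y, _MU_FLOOR) / mu), 0.0)
    pois = ylogy - (Y - mu)
    r = 1.0 / np.maximum(phi_col, _PHI_POISSON)
    nb = ylogy - (Y + r) * np.log((Y + r) / (mu + r))
    return 2.0 * np.where(phi_col < _PHI_POISSON, pois, nb).sum(axis=1)


# ---------------------------------------------------------------------------
# batched IRLS
# ---------------------------------------------------------------------------

def _irls(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi,
          tol: float = 1e-8, max_iter: int = 100):
    """Fit log-link NB GLMs for all genes at once.

    Returns (beta (G,p), mu (G,n), loglik (G,), deviance (G,), converged (G,)).
    Convergence: relative deviance change < tol.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise InputError("design matrix is rank deficient")
    phi_col = _as_phi_col(phi, G)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    mu = Y + 0.5
    eta = np.log(mu)
    dev = _deviance(Y, mu, phi_col)
    delta = np.full(G, np.inf)
    eye = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        W = mu / (1.0 + phi_col * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
        XtWz = np.einsum("ni,gn,gn->gi", X, W, z, optimize=True)
        beta = np.linalg.solve(XtWX + eye, XtWz[..., None])[..., 0]
        eta = np.clip(beta @ X.T + offset[None, :], -40.0, 40.0)
        mu = np.exp(eta)
        new_dev = _deviance(Y, mu, phi_col)
        delta = np.abs(new_dev - dev) / (np.abs(new_dev) + 0.1)
        dev = new_dev
        if np.all(delta < tol):
            break
    converged = delta < tol
    ll = nb_loglik(Y, mu, phi_col[:, 0])
    return beta, mu, ll, dev, converged


@dataclass
class NBFit:
    """A fitted per-gene NB GLM."""

    coef: np.ndarray
    loglik: float
    fitted: np.ndarray
    deviance: float
    converged: bool
    dispersion: float
    X: np.ndarray = field(repr=False)


def fit_nb_glm(y, X, offsets=None, dispersion: float = 0.0,
               tol: float = 1e-8, max_iter: int = 100) -> NBFit:
    """Fit one gene's log-link NB GLM by IRLS.

    With ``dispersion=0`` this is the Poisson GLM.  The returned
    log-likelihood is the exact NB/Poisson log pmf at the fitted means.
    """
    y = np.asarray(y, dtype=float)
    if dispersion < 0:
        raise InputError("dispersion must be >= 0")
    beta, mu, ll, dev, conv = _irls(y[None, :], np.asarray(X, float),
                                    offsets, dispersion, tol, max_iter)
    if not conv[0]:
        logger.warning("IRLS did not converge within %d iterations", max_iter)
    return NBFit(coef=beta[0], loglik=float(ll[0]), fitted=mu[0],
                 deviance=float(dev[0]), converged=bool(conv[0]),
                 dispersion=float(dispersion), X=np.asarray(X, float))


def lrt_stage(full: NBFit, reduced: NBFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p-value)."""
    if abs(full.dispersion - reduced.dispersion) > 1e-12:
        raise InputError("fits use different dispersions")
    Xf, Xr = full.X, reduced.X
    stacked = np.hstack([Xf, Xr])
    if np.linalg.matrix_rank(stacked) > np.linalg.matrix_rank(Xf):
        raise InputError("reduced design is not nested in the full design")
    df = np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr)
    if df <= 0:
        raise InputError("full design does not extend the reduced design")
    lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return lr, int(df), float(stats.chi2.sf(lr, df))


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _apl(Y, X, offset, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood at dispersion phi (per gene)."""
    G = Y.shape[0]
    phi_col = _as_phi_col(phi, G)
    _, mu, ll, _, _ = _irls(Y, X, offset, phi_col[:, 0])
    W = mu / (1.0 + phi_col * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
    _, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * logdet


_PHI_LO, _PHI_HI = 1e-6, 10.0
DEFAULT_PHI_GRID = np.logspace(np.log10(_PHI_LO), np.log10(_PHI_HI), 43)
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_max_vec(objective, n: int, iters: int = 35) -> np.ndarray:
    """Vectorized golden-section maximization over log-phi, one value per gene.

    ``objective(phi_vector)`` returns one score per gene; the per-gene score
    is assumed unimodal in log phi on [_PHI_LO, _PHI_HI].
    """
    a = np.full(n, np.log(_PHI_LO))
    b = np.full(n, np.log(_PHI_HI))
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1 = objective(np.exp(x1))
    f2 = objective(np.exp(x2))
    for _ in range(iters):
        take1 = f1 >= f2  # left probe better -> keep [a, x2]
        a = np.where(take1, a, x1)
        b = np.where(take1, x2, b)
        probe = np.where(take1, b - _GOLDEN * (b - a), a + _GOLDEN * (b - a))
        fp = objective(np.exp(probe))
        # surviving interior point: old x1 (else branch) / old x2 (take1)
        x1, x2, f1, f2 = (
            np.where(take1, probe, x2),
            np.where(take1, x1, probe),
            np.where(take1, fp, f2),
            np.where(take1, f1, fp),
        )
    return np.exp((a + b) / 2.0)


def estimate_dispersion(
    counts_a: StageMatrix,
    counts_b: StageMatrix,
    mode: str = "shrunk",
    prior_weight: float = 10.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-gene NB dispersion for the stage + replicate design.

    modes
    -----
    ``genewise``
        Maximize each gene's Cox-Reid adjusted profile likelihood.
    ``common``
        One value maximizing the average adjusted profile likelihood.
    ``shrunk`` (default)
        Maximize APL_g + prior_weight * mean-APL, pulling noisy genewise
        values toward the common curve's optimum.

    Returns (phi array over genes, info dict).  All-zero genes get phi = 0
    and are flagged, not estimated.
    """
    Y, design = _stack_counts(counts_a, counts_b)
    return dispersion_from_counts(Y, design, mode=mode,
                                  prior_weight=prior_weight, grid=grid)


def dispersion_from_counts(Y, design: DesignSpec, mode: str = "shrunk",
                           prior_weight: float = 10.0,
                           grid: np.ndarray | None = None):
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if design.residual_df < 1:
        raise InputError(
            "design leaves no residual degrees of freedom; "
            "dispersion is not identifiable (single observation per condition)"
        )
    if mode not in ("genewise", "common", "shrunk"):
        raise InputError(f"unknown dispersion mode {mode!r}")
    X, offset = design.X_full, design.offsets
    G = Y.shape[0]
    nonzero = Y.sum(axis=1) > 0
    Ynz = Y[nonzero]
    phi = np.zeros(G)
    info = {"mode": mode, "n_all_zero": int((~nonzero).sum())}

    if Ynz.shape[0] == 0:
        return phi, info

    if mode == "common":
        def neg_mean_apl(logphi):
            return -float(_apl(Ynz, X, offset, np.exp(logphi)).mean())

        res = minimize_scalar(neg_mean_apl,
                              bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
                              method="bounded", options={"xatol": 1e-4})
        common = float(np.exp(res.x))
        # a boundary solution at the lower bound means "effectively Poisson"
        if -neg_mean_apl(np.log(_PHI_LO)) >= -res.fun - 1e-9:
            common = 0.0
        phi[nonzero] = common
        info["common"] = common
        return phi, info

    Gnz = Ynz.shape[0]
    if mode == "genewise":
        def objective(phi_vec):
            return _apl(Ynz, X, offset, phi_vec)
    else:
        # smooth interpolant of the average APL over genes (the common curve)
        grid = DEFAULT_PHI_GRID if grid is None else np.asarray(grid, dtype=float)
        mean_apl = np.array([float(_apl(Ynz, X, offset, g).mean()) for g in grid])
        log_grid = np.log(grid)

        def objective(phi_vec):
            prior = np.interp(np.log(phi_vec), log_grid, mean_apl)
            return _apl(Ynz, X, offset, phi_vec) + prior_weight * prior

    est = _golden_max_vec(objective, Gnz)
    est[est < 2.0 * _PHI_LO] = 0.0  # boundary solutions are effectively Poisson
    phi[nonzero] = est
    return phi, info


def _stack_counts(counts_a: StageMatrix, counts_b: StageMatrix):
    for sm in (counts_a, counts_b):
        if sm.value_kind != "counts":
            raise InputError("differential testing requires raw counts, "
                             "not RPKM/normalized values")
    if set(counts_a.gene_ids) != set(counts_b.gene_ids):
        raise InputError("replicates have different gene universes")
    counts_b = counts_b.subset(counts_a.gene_ids)
    if counts_a.stages != counts_b.stages:
        raise InputError("replicates have different stage columns")
    Y = np.hstack([counts_a.values.to_numpy(float),
                   counts_b.values.to_numpy(float)])
    design = build_design(counts_a.stages, counts_a.mapped_totals,
                          counts_b.mapped_totals)
    return Y, design


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("p_values must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# genewise table
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Genewise LRT table plus run metadata."""

    table: pd.DataFrame
    design: DesignSpec
    dispersion_info: dict
    alpha: float
    n_nonconverged: int

    @property
    def n_significant(self) -> int:
        return int((self.table["fdr"] <= self.alpha).sum())

    def significant_genes(self) -> set:
        t = self.table
        return set(t.index[t["fdr"] <= self.alpha])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def de_test(
    counts_a: StageMatrix,
    counts_b: StageMatrix,
    dispersion_mode: str = "shrunk",
    alpha: float = 0.05,
    prior_weight: float = 10.0,
    dispersion=None,
) -> DEResult:
    """Genewise across-stage LRT with BH correction.

    ``dispersion`` may pre-specify phi (scalar or per-gene) and skips
    estimation — useful for calibration studies with known truth.
    Non-converged fits are excluded from testing (p and fdr set to NaN) and
    counted in ``n_nonconverged``.
    """
    Y, design = _stack_counts(counts_a, counts_b)
    gene_ids = counts_a.gene_ids
    if dispersion is None:
        phi, disp_info = dispersion_from_counts(
            Y, design, mode=dispersion_mode, prior_weight=prior_weight)
    else:
        phi = _as_phi_col(dispersion, Y.shape[0])[:, 0]
        disp_info = {"mode": "fixed"}

    beta_f, _, ll_full, _, conv_f = _irls(Y, design.X_full, design.offsets, phi)
    _, _, ll_red, _, conv_r = _irls(Y, design.X_reduced, design.offsets, phi)
    converged = conv_f & conv_r
    lr = np.maximum(0.0, 2.0 * (ll_full - ll_red))
    df = design.df_test
    p = stats.chi2.sf(lr, df)
    p[~converged] = np.nan

    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])

    ns = len(design.stages)
    log2_effects = beta_f[:, 1:ns] / np.log(2.0)
    table = pd.DataFrame(
        {
            "lr_stat": lr,
            "df": df,
            "p_value": p,
            "fdr": fdr,
            "dispersion": phi,
            "converged": converged,
        },
        index=gene_ids,
    )
    for j, stage in enumerate(design.stages[1:]):
        table[f"log2_effect_{stage}"] = log2_effects[:, j]
    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("%d genes excluded from testing (IRLS non-convergence)",
                       n_bad)
    return DEResult(table=table, design=design, dispersion_info=disp_info,
                    alpha=alpha, n_nonconverged=n_bad)
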