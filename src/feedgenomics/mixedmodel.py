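"""Average-information REML and BLUP for the animal model with a common
environmental effect.

The model is ``y = Xb + Za + Wc + e`` with ``a ~ N(0, K sigma_a2)`` for a
relationship matrix K (pedigree A, genomic G, or single-step H),
``c ~ N(0, I sigma_c2)`` for the shared-aquarium effect and i.i.d.
residuals.  Variance components are estimated by AI-REML with step
halving and an EM-style fallback whenever an average-information step
leaves the parameter space; breeding values come from Henderson's
mixed-model equations at the estimates.  Heritability is
``sigma_a2 / (sigma_a2 + sigma_c2 + sigma_e2)`` and the common-environment
ratio ``c2`` is the analogous fraction; their standard errors use the
delta method on the inverse average-information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from feedgenomics.kinship import KinshipMatrix


# ---------------------------------------------------------------------------
# generic AI-REML core: V(theta) = sum_i theta_i C_i
# ---------------------------------------------------------------------------

def _reml_pieces(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Return (P, Py, logL) for one V; raises LinAlgError if V not PD."""
    n = len(y)
    c = np.linalg.cholesky(V)
    Vinv = np.linalg.solve(c.T, np.linalg.solve(c, np.eye(n)))
    logdet_V = 2.0 * np.log(np.diag(c)).sum()
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cx = np.linalg.cholesky(XtVinvX)
    logdet_X = 2.0 * np.log(np.diag(cx)).sum()
    P = Vinv - VinvX @ np.linalg.solve(cx.T, np.linalg.solve(cx, VinvX.T))
    Py = P @ y
    logL = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return P, Py, logL


def _fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    comps: list[np.ndarray],
    theta0: np.ndarray,
    var_mask: np.ndarray,
    floor: float,
    projector=None,
    max_iter: int = 200,
    tol: float = 1e-8,
):
    """Maximise the restricted likelihood of V = sum theta_i C_i.

    ``var_mask`` marks parameters that are variances (kept >= floor); the
    optional ``projector`` repairs a candidate theta (e.g. bends covariance
    blocks back to PSD) and returns (theta, bent_flag).
    """
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is singular")
    theta = theta0.astype(float).copy()
    k = len(comps)
    bent = False

    def clean(t):
        t = t.copy()
        t[var_mask] = np.maximum(t[var_mask], floor)
        if projector is not None:
            t, b = projector(t)
        else:
            b = False
        return t, b

    theta, _ = clean(theta)

    def build_V(t):
        V = np.zeros_like(comps[0])
        for ti, Ci in zip(t, comps):
            V += ti * Ci
        return V

    P, Py, logL = _reml_pieces(y, X, build_V(theta))
    history = [logL]
    converged = False
    n_iter = 0
    AI = np.eye(k)
    for n_iter in range(1, max_iter + 1):
        CiPy = [Ci @ Py for Ci in comps]
        score = np.array(
            [-0.5 * (float(np.sum(P * Ci)) - float(Py @ cpy)) for Ci, cpy in zip(comps, CiPy)]
        )
        AI = np.empty((k, k))
        PCiPy = [P @ cpy for cpy in CiPy]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(CiPy[i] @ PCiPy[j])
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(k), score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diag(AI), 1e-10)

        accepted = False
        step = 1.0
        for _ in range(12):
            cand, b = clean(theta + step * delta)
            try:
                P_c, Py_c, logL_c = _reml_pieces(y, X, build_V(cand))
            except np.linalg.LinAlgError:
                step /= 2.0
                continue
            if logL_c >= logL - 1e-10:
                accepted = True
                bent = bent or b
                break
            step /= 2.0
        if not accepted:
            # EM-style fixed-point update for the variance parameters; it
            # preserves positivity and cannot overshoot the boundary.
            cand = theta.copy()
            for i in range(k):
                if var_mask[i]:
                    tr = float(np.sum(P * comps[i]))
                    if tr > 0:
                        cand[i] = theta[i] * float(Py @ CiPy[i]) / tr
            cand, b = clean(cand)
            try:
                P_c, Py_c, logL_c = _reml_pieces(y, X, build_V(cand))
            except np.linalg.LinAlgError:
                converged = False
                break
            if logL_c < logL - 1e-6 * (1 + abs(logL)):
                break  # no direction improves: stop at current theta
            bent = bent or b

        rel = abs(logL_c - logL) / (1.0 + abs(logL))
        theta, P, Py, logL = cand, P_c, Py_c, logL_c
        history.append(logL)
        if rel < tol:
            converged = True
            break

    try:
        ai_inv = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        ai_inv = np.full((k, k), np.nan)
    return {
        "theta": theta,
        "loglik": logL,
        "n_iter": n_iter,
        "converged": converged,
        "ai_inv": ai_inv,
        "bent": bent,
        "history": history,
        "P": P,
        "Py": Py,
    }


# ---------------------------------------------------------------------------
# results container and the heritability formula
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance components and their derived ratios."""

    sigma_a2: float
    sigma_c2: float | None
    sigma_e2: float
    h2: float
    c2: float | None
    se_h2: float | None = None
    se_c2: float | None = None
    sigma_a12: float | None = None  # bivariate only
    rg: float | None = None
    se_rg: float | None = None
    converged: bool = True
    n_iterations: int = 0
    loglik: float = float("nan")

    def as_row(self) -> dict:
        return {
            "sigma_a2": self.sigma_a2,
            "sigma_c2": self.sigma_c2,
            "sigma_e2": self.sigma_e2,
            "h2": self.h2,
            "c2": self.c2,
            "se_h2": self.se_h2,
            "se_c2": self.se_c2,
            "rg": self.rg,
            "se_rg": self.se_rg,
            "converged": self.converged,
        }


def heritability(vc) -> tuple[float, float]:
    """h2 = sigma_a2 / (sigma_a2 + sigma_c2 + sigma_e2); c2 analogous.

    Accepts a :class:`VarianceComponents` or an (a2, c2, e2) triple.
    """
    if isinstance(vc, VarianceComponents):
        a2, c2, e2 = vc.sigma_a2, vc.sigma_c2 or 0.0, vc.sigma_e2
    else:
        a2, c2, e2 = vc
        c2 = c2 or 0.0
    total = a2 + c2 + e2
    if total <= 0:
        raise ValueError("total variance must be positive")
    return a2 / total, c2 / total


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def design_matrix(pheno: pd.DataFrame, fixed=("sex", "batch")) -> np.ndarray:
    """Intercept plus drop-first dummy columns for each fixed factor."""
    cols = [np.ones(len(pheno))]
    for f in fixed:
        d = pd.get_dummies(pheno[f].astype(str), drop_first=True, dtype=float)
        cols.extend(d[c].to_numpy() for c in d.columns)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is singular (confounded factors)")
    return X


def _group_incidence(groups) -> tuple[np.ndarray, list]:
    labels = pd.Series(groups).astype(str).to_numpy()
    levels = sorted(set(labels))
    W = (labels[:, None] == np.array(levels)[None, :]).astype(float)
    return W, levels


def _resolve_kinship(kinship, record_ids, n_records):
    """Return (K, Kinv_or_None, kin_ids, record->kin index)."""
    if kinship is None:
        ids = [str(i) for i in (record_ids if record_ids is not None else range(n_records))]
        return np.eye(n_records), np.eye(n_records), ids, np.arange(n_records)
    if isinstance(kinship, np.ndarray):
        kinship = KinshipMatrix(kind="K", ids=[str(i) for i in range(len(kinship))], values=kinship)
    ids = kinship.ids
    pos = {a: i for i, a in enumerate(ids)}
    if record_ids is None:
        if len(ids) != n_records:
            raise ValueError("kinship size differs from record count; pass record_ids")
        idx = np.arange(n_records)
    else:
        try:
            idx = np.array([pos[str(a)] for a in record_ids])
        except KeyError as e:
            raise ValueError(f"record id {e} has no kinship row") from None
    if kinship.kind == "Hinv":
        Kinv = kinship.values
        K = np.linalg.inv(Kinv)
        K = (K + K.T) / 2.0
    else:
        K, Kinv = kinship.values, None
    return K, Kinv, ids, idx


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None,
    Kinv: np.ndarray | None,
    idx: np.ndarray,
    groups,
    sigma_a2: float,
    sigma_c2: float | None,
    sigma_e2: float,
):
    """Henderson's mixed-model equations at fixed variance components.

    Returns (beta, ebv for every kinship row, common effects or None).
    Works from K^-1, so a single-step inverse can be passed directly.
    """
    from feedgenomics.kinship import _safe_inverse

    n = len(y)
    q = len(K) if K is not None else len(Kinv)
    if Kinv is None:
        # G with observed allele frequencies is singular (centred columns
        # sum to zero), so a small blend toward I is applied when needed
        Kinv, _ = _safe_inverse(K, "relationship matrix")
    Z = np.zeros((n, q))
    Z[np.arange(n), idx] = 1.0
    lam_a = sigma_e2 / max(sigma_a2, 1e-12)
    blocks_X = [X, Z]
    if groups is not None and sigma_c2 is not None:
        W, levels = _group_incidence(groups)
        blocks_X.append(W)
        lam_c = sigma_e2 / max(sigma_c2, 1e-12)
    else:
        W, levels, lam_c = None, None, None
    T = np.hstack(blocks_X)
    LHS = T.T @ T
    p = X.shape[1]
    LHS[p : p + q, p : p + q] += Kinv * lam_a
    if W is not None:
        s = W.shape[1]
        LHS[p + q :, p + q :] += np.eye(s) * lam_c
    RHS = T.T @ y
    try:
        sol = np.linalg.solve(LHS, RHS)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(LHS, RHS, rcond=None)
    beta = sol[:p]
    a_hat = sol[p : p + q]
    c_hat = sol[p + q :] if W is not None else None
    return beta, a_hat, (c_hat, levels) if W is not None else (None, None)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class MixedModelREML(BaseEstimator):
    """Animal-model REML estimator with a fit/predict interface.

    Parameters
    ----------
    include_common_env : bool
        Fit the shared-aquarium variance component when a grouping is
        supplied (dropped automatically when it has a single level).
    max_iter, tol : int, float
        AI-REML iteration cap and relative log-likelihood convergence
        tolerance.
    var_floor_ratio : float
        Variances are constrained to at least this fraction of the
        phenotypic variance.

    After ``fit`` the estimated components are available as
    ``sigma_a2_``, ``sigma_c2_``, ``sigma_e2_``, ``h2_``, ``c2_`` (with
    ``se_h2_``/``se_c2_``), ``beta_``, ``ebv_`` (a Series over every
    kinship id, phenotyped or not), ``loglik_``, ``n_iter_`` and
    ``converged_``.
    """

    def __init__(
        self,
        include_common_env: bool = True,
        max_iter: int = 200,
        tol: float = 1e-8,
        var_floor_ratio: float = 1e-8,
    ):
        self.include_common_env = include_common_env
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor_ratio = var_floor_ratio

    def fit(self, X, y, kinship=None, record_ids=None, groups=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("X and y have different record counts")
        K, Kinv, kin_ids, idx = _resolve_kinship(kinship, record_ids, n)
        ZKZt = K[np.ix_(idx, idx)]

        use_c = self.include_common_env and groups is not None
        if use_c and len(set(pd.Series(groups).astype(str))) < 2:
            use_c = False
        comps = [ZKZt]
        if use_c:
            W, _ = _group_incidence(groups)
            comps.append(W @ W.T)
        comps.append(np.eye(n))

        vp = float(np.var(y))
        floor = self.var_floor_ratio * vp
        k = len(comps)
        theta0 = np.full(k, vp / k)
        res = _fit_reml(
            y, X, comps, theta0,
            var_mask=np.ones(k, dtype=bool),
            floor=floor,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        th = res["theta"]
        self.sigma_a2_ = float(th[0])
        self.sigma_c2_ = float(th[1]) if use_c else None
        self.sigma_e2_ = float(th[-1])
        self.h2_, self.c2_ = heritability(
            (self.sigma_a2_, self.sigma_c2_, self.sigma_e2_)
        )
        if not use_c:
            self.c2_ = None
        self.loglik_ = res["loglik"]
        self.loglik_path_ = res["history"]
        self.n_iter_ = res["n_iter"]
        self.converged_ = res["converged"]
        self.varcomp_cov_ = res["ai_inv"]
        self.se_h2_, self.se_c2_ = self._ratio_ses(th, res["ai_inv"], use_c)

        beta, a_hat, (c_hat, levels) = solve_mme(
            y, X, K, Kinv, idx, groups if use_c else None,
            self.sigma_a2_, self.sigma_c2_, self.sigma_e2_,
        )
        self.beta_ = beta
        self.ebv_ = pd.Series(a_hat, index=kin_ids, name="ebv")
        self.common_effects_ = (
            pd.Series(c_hat, index=levels, name="common_effect") if c_hat is not None else None
        )
        self.record_index_ = idx
        return self

    @staticmethod
    def _ratio_ses(theta, ai_inv, use_c):
        """Delta-method SEs of h2 and c2 from the AI-matrix inverse."""
        if not np.all(np.isfinite(ai_inv)):
            return None, None
        total = theta.sum()
        k = len(theta)
        g_h = np.full(k, -theta[0] / total**2)
        g_h[0] += 1.0 / total
        se_h = float(np.sqrt(max(g_h @ ai_inv @ g_h, 0.0)))
        if use_c:
            g_c = np.full(k, -theta[1] / total**2)
            g_c[1] += 1.0 / total
            se_c = float(np.sqrt(max(g_c @ ai_inv @ g_c, 0.0)))
        else:
            se_c = None
        return se_h, se_c

    def predict(self, ids=None) -> np.ndarray:
        """EBVs for the requested animal ids (default: every kinship id)."""
        if not hasattr(self, "ebv_"):
            raise RuntimeError("estimator is not fitted")
        if ids is None:
            return self.ebv_.to_numpy()
        return self.ebv_.loc[[str(i) for i in ids]].to_numpy()

    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(
            sigma_a2=self.sigma_a2_,
            sigma_c2=self.sigma_c2_,
            sigma_e2=self.sigma_e2_,
            h2=self.h2_,
            c2=self.c2_,
            se_h2=self.se_h2_,
            se_c2=self.se_c2_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            loglik=self.loglik_,
        )


# ---------------------------------------------------------------------------
# module-level wrappers (spec-level operations)
# ---------------------------------------------------------------------------

def reml_fit(
    pheno: pd.DataFrame,
    response: str,
    kinship,
    fixed=("sex", "batch"),
    common: str | None = "aquarium",
    **estimator_kwargs,
) -> tuple[VarianceComponents, MixedModelREML]:
    """Fit the animal model for one trait from a phenotype table.

    Rows with a missing response or an ``<response>_outlier`` flag are
    dropped; fixed factors become dummy columns with an intercept.
    """
    from feedgenomics.traits import trait_values

    rows = trait_values(pheno, response)
    y = rows[response].to_numpy(dtype=float)
    X = design_matrix(rows, fixed)
    groups = rows[common].to_numpy() if common is not None and common in rows.columns else None
    est = MixedModelREML(**estimator_kwargs).fit(
        X, y, kinship=kinship, record_ids=rows["animal"].tolist(), groups=groups
    )
    return est.variance_components(), est


def predict_ebv(
    pheno: pd.DataFrame,
    response: str,
    kinship,
    vc: VarianceComponents,
    fixed=("sex", "batch"),
    common: str | None = "aquarium",
    mask_animals=None,
) -> pd.Series:
    """EBVs from Henderson's equations at fixed variance components.

    ``mask_animals`` drops the listed animals' phenotypes from the
    right-hand side (cross-validation masking) while their breeding values
    are still predicted through the relationship matrix.
    """
    from feedgenomics.traits import trait_values

    rows = trait_values(pheno, response)
    if mask_animals is not None:
        masked = set(str(a) for a in mask_animals)
        rows = rows.loc[~rows["animal"].astype(str).isin(masked)]
    y = rows[response].to_numpy(dtype=float)
    X = design_matrix(rows, fixed)
    groups = rows[common].to_numpy() if common is not None and common in rows.columns else None
    use_c = groups is not None and vc.sigma_c2 is not None and len(set(map(str, groups))) > 1
    K, Kinv, kin_ids, idx = _resolve_kinship(kinship, rows["animal"].tolist(), len(rows))
    _, a_hat, _ = solve_mme(
        y, X, K, Kinv, idx, groups if use_c else None,
        vc.sigma_a2, vc.sigma_c2 if use_c else None, vc.sigma_e2,
    )
    return pd.Series(a_hat, index=kin_ids, name="ebv")


def reml_fit_bivariate(
    pheno: pd.DataFrame,
    trait_1: str,
    trait_2: str,
    kinship,
    fixed=("sex", "batch"),
    common: str | None = "aquarium",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Two-trait REML with unstructured genetic and residual covariances.

    The common-environment component is kept diagonal across traits.  The
    genetic correlation is ``rg = sigma_a12 / sqrt(sigma_a1^2 sigma_a2^2)``
    with a delta-method SE; non-PSD iterates of the 2x2 blocks are bent
    back to the parameter space (eigenvalue clipping) and flagged.
    """
    from feedgenomics.traits import trait_values

    rows = [trait_values(pheno, t) for t in (trait_1, trait_2)]
    if not set(rows[0]["animal"]) & set(rows[1]["animal"]):
        raise ValueError("traits share no animals; covariances are not estimable")
    ys = [r[t].to_numpy(dtype=float) for r, t in zip(rows, (trait_1, trait_2))]
    Xs = [design_matrix(r, fixed) for r in rows]
    n1, n2 = len(ys[0]), len(ys[1])
    n = n1 + n2
    y = np.concatenate(ys)
    X = np.zeros((n, Xs[0].shape[1] + Xs[1].shape[1]))
    X[:n1, : Xs[0].shape[1]] = Xs[0]
    X[n1:, Xs[0].shape[1] :] = Xs[1]

    if isinstance(kinship, np.ndarray):
        kinship = KinshipMatrix(
            kind="K", ids=[str(i) for i in range(len(kinship))], values=kinship
        )
    if kinship.kind == "Hinv":
        K = np.linalg.inv(kinship.values)
        K = (K + K.T) / 2.0
    else:
        K = kinship.values
    kin_ids = kinship.ids
    pos = {a: i for i, a in enumerate(kin_ids)}
    idx1 = np.array([pos[str(a)] for a in rows[0]["animal"]])
    idx2 = np.array([pos[str(a)] for a in rows[1]["animal"]])
    K11 = K[np.ix_(idx1, idx1)]
    K22 = K[np.ix_(idx2, idx2)]
    K12 = K[np.ix_(idx1, idx2)]

    def pad(block, where) -> np.ndarray:
        M = np.zeros((n, n))
        if where == "11":
            M[:n1, :n1] = block
        elif where == "22":
            M[n1:, n1:] = block
        else:
            M[:n1, n1:] = block
            M[n1:, :n1] = block.T
        return M

    same = (
        rows[0]["animal"].astype(str).to_numpy()[:, None]
        == rows[1]["animal"].astype(str).to_numpy()[None, :]
    ).astype(float)

    comps = [
        pad(K11, "11"),  # g11
        pad(K12, "12"),  # g12
        pad(K22, "22"),  # g22
        pad(np.eye(n1), "11"),  # r11
        pad(same, "12"),  # r12
        pad(np.eye(n2), "22"),  # r22
    ]
    names = ["g11", "g12", "g22", "r11", "r12", "r22"]
    var_mask = [True, False, True, True, False, True]

    use_c = common is not None and common in pheno.columns
    if use_c:
        for r in rows:
            W, _ = _group_incidence(r[common])
            comps.append(pad(W @ W.T, "11" if r is rows[0] else "22"))
        names += ["c1", "c2"]
        var_mask += [True, True]
    var_mask = np.array(var_mask)

    vps = [float(np.var(v)) for v in ys]
    floor = 1e-8 * min(vps)
    # start the covariances at the phenotypic correlation of the shared
    # animals, so near-degenerate pairs (e.g. a trait against itself) do
    # not begin stranded on the wrong side of the parameter space
    left = rows[0][["animal", trait_1]].rename(columns={trait_1: "y1"})
    right = rows[1][["animal", trait_2]].rename(columns={trait_2: "y2"})
    shared = left.merge(right, on="animal")
    rp = 0.0
    if len(shared) > 2:
        rp = float(np.corrcoef(shared["y1"], shared["y2"])[0, 1])
        if not np.isfinite(rp):
            rp = 0.0
        rp = float(np.clip(rp, -0.95, 0.95))
    cross = np.sqrt(vps[0] * vps[1])
    theta0 = np.array(
        [0.4 * vps[0], 0.4 * rp * cross, 0.4 * vps[1],
         0.5 * vps[0], 0.5 * rp * cross, 0.5 * vps[1]]
        + ([0.1 * vps[0], 0.1 * vps[1]] if use_c else [])
    )

    def projector(t):
        bent = False
        t = t.copy()
        for i0, i1, i2 in ((0, 1, 2), (3, 4, 5)):
            B = np.array([[t[i0], t[i1]], [t[i1], t[i2]]])
            w, Q = np.linalg.eigh(B)
            if w.min() < floor:
                B = Q @ np.diag(np.maximum(w, floor)) @ Q.T
                t[i0], t[i1], t[i2] = B[0, 0], B[0, 1], B[1, 1]
                bent = True
        return t, bent

    res = _fit_reml(
        y, X, comps, theta0, var_mask=var_mask, floor=floor,
        projector=projector, max_iter=max_iter, tol=tol,
    )
    th = dict(zip(names, res["theta"]))
    g11, g12, g22 = th["g11"], th["g12"], th["g22"]
    rg = g12 / np.sqrt(g11 * g22)
    ai_inv = res["ai_inv"]
    se_rg = None
    if np.all(np.isfinite(ai_inv)):
        grad = np.zeros(len(names))
        grad[0] = -rg / (2 * g11)
        grad[1] = 1.0 / np.sqrt(g11 * g22)
        grad[2] = -rg / (2 * g22)
        se_rg = float(np.sqrt(max(grad @ ai_inv @ grad, 0.0)))

    c1 = th.get("c1")
    h2_1, c2_1 = heritability((g11, c1, th["r11"]))
    return VarianceComponents(
        sigma_a2=g11,
        sigma_c2=c1,
        sigma_e2=th["r11"],
        h2=h2_1,
        c2=c2_1 if use_c else None,
        sigma_a12=g12,
        rg=float(np.clip(rg, -1.0, 1.0)),
        se_rg=se_rg,
        converged=res["converged"],
        n_iterations=res["n_iter"],
        loglik=res["loglik"],
    )
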