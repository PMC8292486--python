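"""Social (direct + indirect) genetic effects model, fitted by REML.

Model for record i of a group-housed animal:

    y = X b + Z_D a_D + Z_S a_S + W l + V g + e

with [a_D; a_S] ~ N(0, C (x) K) where C is the 2x2 direct/social genetic
(co)variance matrix and K a relationship matrix (genomic by default), litter
effects l ~ N(0, I s2_l), pen/group effects g ~ N(0, I s2_g), residual
e ~ N(0, I s2_e). Z_D maps records to the animal's own additive effect; Z_S
carries a 1 in the column of every pen mate, so a row sums to pen size - 1.

Estimation is average-information REML with safeguarding: a proposed AI step
is projected into the parameter space (variance floor, PSD genetic block) and
backtracked until the restricted log-likelihood does not decrease; if the AI
direction fails entirely an EM step is taken. Accepted iterations therefore
have non-decreasing log-likelihood. EBVs and prediction-error variances come
from the mixed-model equations at the REML optimum; accuracies are
r = sqrt(1 - PEV / sigma2) with the effect-specific genetic variance in the
denominator, and deregressed EBVs are g_i / r_i^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd


class SingularModelError(ValueError):
    """The model's fixed or random structure is confounded."""


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignSet:
    """Phenotype vector plus incidence matrices for the social model."""

    y: np.ndarray
    X: np.ndarray
    Z_D: np.ndarray
    Z_S: np.ndarray
    W: np.ndarray
    V: np.ndarray
    ids: list[str]
    fixed_names: list[str]
    litter_levels: list
    group_levels: list
    log: list[str] = field(default_factory=list)


def _dummy(codes: pd.Series, prefix: str) -> tuple[np.ndarray, list[str], list]:
    levels = list(pd.unique(codes))
    mat = np.zeros((len(codes), len(levels)))
    lut = {lv: k for k, lv in enumerate(levels)}
    for i, v in enumerate(codes):
        mat[i, lut[v]] = 1.0
    names = [f"{prefix}[{lv}]" for lv in levels]
    return mat, names, levels


def build_design(
    cohort: pd.DataFrame,
    trait: pd.Series | np.ndarray | str,
    traits: pd.DataFrame | None = None,
    fixed_factors: tuple[str, ...] = ("sex", "test_ym", "birth_ym"),
) -> DesignSet:
    """Assemble y, X, Z_D, Z_S, W, V for one trait.

    ``trait`` may be a column name into ``traits`` (keyed by id) or a vector
    aligned with ``cohort``. Records missing the phenotype, pen or litter are
    excluded with a warning; the random-effect columns span all retained
    individuals. Single-observation factor levels are retained and logged.
    """
    df = cohort.reset_index(drop=True).copy()
    if isinstance(trait, str):
        if traits is None:
            raise ValueError("trait given by name requires a traits table")
        df = df.merge(traits[["id", trait]], on="id", how="left")
        yv = df[trait].to_numpy(dtype=float)
    else:
        yv = np.asarray(trait, dtype=float)
        if yv.shape[0] != len(df):
            raise ValueError("trait vector does not match cohort length")

    log: list[str] = []
    ok = np.isfinite(yv) & df["pen"].notna().to_numpy() & df["litter"].notna().to_numpy()
    n_drop = int((~ok).sum())
    if n_drop:
        msg = f"excluded {n_drop} records with missing phenotype/pen/litter"
        warnings.warn(msg, stacklevel=2)
        log.append(msg)
    df = df.loc[ok].reset_index(drop=True)
    yv = yv[ok]
    n = len(df)

    X_parts = [np.ones((n, 1))]
    names = ["intercept"]
    for fac in fixed_factors:
        codes = df[fac]
        levels = pd.unique(codes)
        if len(levels) < 2:
            log.append(f"fixed factor {fac} has a single level; dropped")
            continue
        # drop first level as the reference
        mat, nm, lv = _dummy(codes, fac)
        counts = mat.sum(axis=0)
        singles = [str(l) for l, c in zip(lv, counts) if c == 1]
        if singles:
            log.append(f"fixed factor {fac}: single-observation levels retained: {singles}")
        X_parts.append(mat[:, 1:])
        names.extend(nm[1:])
    X = np.hstack(X_parts)

    Z_D = np.eye(n)
    pen = df["pen"].to_numpy()
    Z_S = (pen[:, None] == pen[None, :]).astype(float)
    np.fill_diagonal(Z_S, 0.0)
    W, _, litter_levels = _dummy(df["litter"], "litter")
    V, _, group_levels = _dummy(df["pen"], "pen")
    return DesignSet(
        y=yv, X=X, Z_D=Z_D, Z_S=Z_S, W=W, V=V,
        ids=list(df["id"]), fixed_names=names,
        litter_levels=litter_levels, group_levels=group_levels, log=log,
    )


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _bend_psd(K: np.ndarray, rel_floor: float = 1e-8) -> tuple[np.ndarray, int]:
    """Clip eigenvalues below rel_floor * mean(diag) to that floor."""
    w, Q = np.linalg.eigh(K)
    floor = rel_floor * max(np.trace(K) / K.shape[0], 1e-12)
    n_bent = int((w < floor).sum())
    if n_bent:
        w = np.maximum(w, floor)
        K = (Q * w) @ Q.T
    return K, n_bent


class _REMLState:
    """Dense-V REML with analytic derivative matrices.

    V(theta) = sum_k theta_k A_k; the A_k are precomputed once. Parameters are
    ordered [c_DD, c_DS, c_SS, s2_litter, s2_group, s2_e], with inactive
    components removed.
    """

    def __init__(self, design: DesignSet, K: np.ndarray,
                 include_social: bool, include_litter: bool,
                 include_group: bool, estimate_cov: bool):
        self.y = design.y
        self.X = design.X
        n = self.y.shape[0]
        ZD, ZS = design.Z_D, design.Z_S
        KD = ZD @ K @ ZD.T
        self.names: list[str] = ["var_direct"]
        self.A: list[np.ndarray] = [KD]
        self.dims: list[float] = [K.shape[0]]
        self.estimate_cov = estimate_cov and include_social
        self.include_social = include_social
        if include_social:
            ZDKZS = ZD @ K @ ZS.T
            if self.estimate_cov:
                self.names.append("cov_direct_social")
                self.A.append(ZDKZS + ZDKZS.T)
                self.dims.append(K.shape[0])
            self.names.append("var_social")
            self.A.append(ZS @ K @ ZS.T)
            self.dims.append(K.shape[0])
        if include_litter:
            self.names.append("var_litter")
            self.A.append(design.W @ design.W.T)
            self.dims.append(design.W.shape[1])
        if include_group:
            self.names.append("var_group")
            self.A.append(design.V @ design.V.T)
            self.dims.append(design.V.shape[1])
        self.names.append("var_residual")
        self.A.append(np.eye(n))
        self.dims.append(n)
        self.n, self.q = n, np.linalg.matrix_rank(self.X)

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for t, A in zip(theta, self.A):
            V += t * A
        return V

    def loglik(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood via one Cholesky (no P matrix)."""
        from scipy.linalg import cho_factor, cho_solve

        V = self.build_V(theta)
        try:
            cF = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetV = 2.0 * np.log(np.diag(cF[0])).sum()
        ViX = cho_solve(cF, self.X, check_finite=False)
        Viy = cho_solve(cF, self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise SingularModelError(
                "X'V^-1X is singular: fixed effects are confounded "
                f"(columns: {self.X.shape[1]})"
            )
        XtViy = self.X.T @ Viy
        quad = float(self.y @ Viy - XtViy @ np.linalg.solve(XtViX, XtViy))
        return -0.5 * (logdetV + logdetX + quad
                       + (self.n - self.q) * np.log(2 * np.pi))

    def loglik_terms(self, theta: np.ndarray):
        """Return (loglik, P, Py) or (None,)*3 if V is not PD."""
        V = self.build_V(theta)
        try:
            np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None, None, None
        sign, logdetV = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        ViX = Vi @ self.X
        XtViX = self.X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise SingularModelError(
                "X'V^-1X is singular: fixed effects are confounded "
                f"(columns: {self.X.shape[1]})"
            )
        B = np.linalg.solve(XtViX, ViX.T)
        P = Vi - ViX @ B
        Py = P @ self.y
        quad = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetX + quad + (self.n - self.q) * np.log(2 * np.pi))
        return ll, P, Py

    def project(self, theta: np.ndarray, floor: float) -> np.ndarray:
        """Push theta into the admissible region (floors, PSD genetic block)."""
        th = dict(zip(self.names, theta))
        for nm in th:
            if nm != "cov_direct_social":
                th[nm] = max(th[nm], floor)
        if self.estimate_cov:
            cDD, cSS = th["var_direct"], th["var_social"]
            bound = 0.999 * np.sqrt(cDD * cSS)
            th["cov_direct_social"] = float(np.clip(th["cov_direct_social"], -bound, bound))
        return np.array([th[nm] for nm in self.names])


@dataclass
class SocialGeneticResults:
    """REML estimates, EBVs and diagnostics for a fitted social model."""

    model: "SocialGeneticModel"
    varcomps: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    loglik_history: list[float]
    n_bent_eigenvalues: int

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.varcomps)

    @cached_property
    def _mme(self) -> dict[str, np.ndarray]:
        return self.model._solve_mme(self.varcomps)

    @property
    def fixed_effects(self) -> pd.Series:
        return pd.Series(self._mme["b"], index=self.model.design.fixed_names)

    @property
    def ebv_D(self) -> np.ndarray:
        return self._mme["a_D"]

    @property
    def ebv_S(self) -> np.ndarray | None:
        return self._mme.get("a_S")

    @property
    def pev_D(self) -> np.ndarray:
        return self._mme["pev_D"]

    @property
    def pev_S(self) -> np.ndarray | None:
        return self._mme.get("pev_S")

    def accuracy(self, effect: str = "DGE") -> np.ndarray:
        if effect == "DGE":
            return accuracy_from_pev(self.pev_D, self.varcomps["var_direct"])
        if effect == "SGE":
            if self.pev_S is None:
                raise ValueError("model was fitted without the social term")
            return accuracy_from_pev(self.pev_S, self.varcomps["var_social"])
        raise ValueError("effect must be 'DGE' or 'SGE'")

    def deregressed_table(self, trait: str = "trait",
                          r2_floor: float = 0.01) -> pd.DataFrame:
        """Per individual x effect: EBV, accuracy, deregressed EBV, usable flag."""
        frames = []
        effects = ["DGE"] + (["SGE"] if self.ebv_S is not None else [])
        for eff in effects:
            ebv = self.ebv_D if eff == "DGE" else self.ebv_S
            r = self.accuracy(eff)
            debv = np.full_like(ebv, np.nan)
            usable = r**2 >= r2_floor
            debv[usable] = ebv[usable] / (r[usable] ** 2)
            frames.append(
                pd.DataFrame(
                    {
                        "id": self.model.design.ids,
                        "trait": trait,
                        "effect": eff,
                        "ebv": ebv,
                        "accuracy": r,
                        "debv": debv,
                        "usable": usable,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["Social genetic effects model (REML)",
                 "=" * 44,
                 f"records: {len(self.model.design.y)}   "
                 f"fixed-effect columns: {self.model.design.X.shape[1]}",
                 f"converged: {self.converged}   iterations: {self.n_iter}",
                 f"REML log-likelihood: {self.loglik:.6f}",
                 f"bent relationship eigenvalues: {self.n_bent_eigenvalues}",
                 "-" * 44,
                 "variance components:"]
        for k, v in self.varcomps.items():
            lines.append(f"  {k:<22s} {v:12.6f}")
        vp = sum(v for k, v in self.varcomps.items() if k != "cov_direct_social")
        lines.append(f"  {'phenotypic (sum)':<22s} {vp:12.6f}")
        if "var_direct" in self.varcomps and vp > 0:
            lines.append(
                f"  direct h^2: {self.varcomps['var_direct'] / vp:.4f}"
            )
        return "\n".join(lines)


class SocialGeneticModel:
    """Variance-component model with direct and social genetic effects.

    Parameters
    ----------
    design : DesignSet
        From :func:`build_design`.
    K : ndarray
        Relationship matrix among the design's individuals (genomic GRM by
        default usage; a pedigree numerator matrix is equally valid). Bent to
        PSD if needed.
    estimate_cov_ds : bool
        Estimate the direct-social genetic covariance (default) or fix it at 0.
    include_social, include_litter, include_group : bool
        Drop random terms for reduced models.
    normalize_K : bool
        Rescale K to mean diagonal 1 (default). The centered cross-product
        GRM has mean diagonal ~= 2 * mean(p q), so without normalization the
        genetic variances would be on the marker-heterozygosity scale rather
        than the per-individual phenotypic scale.
    """

    def __init__(self, design: DesignSet, K: np.ndarray,
                 estimate_cov_ds: bool = True,
                 include_social: bool = True,
                 include_litter: bool = True,
                 include_group: bool = True,
                 normalize_K: bool = True):
        self.design = design
        n = design.y.shape[0]
        if K.shape != (n, n):
            raise ValueError("K must match the number of records/individuals")
        if n < design.X.shape[1] + 10:
            raise SingularModelError("too few records for the fixed-effect structure")
        K = 0.5 * (K + K.T)
        mean_diag = float(np.trace(K)) / K.shape[0]
        if normalize_K and mean_diag > 0:
            K = K / mean_diag
        self.K, self.n_bent = _bend_psd(K)
        self.include_social = include_social
        self.include_litter = include_litter
        self.include_group = include_group
        self.estimate_cov_ds = estimate_cov_ds
        self._state = _REMLState(design, self.K, include_social,
                                 include_litter, include_group, estimate_cov_ds)

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, trait, K: np.ndarray,
                    traits: pd.DataFrame | None = None, **kwargs
                    ) -> "SocialGeneticModel":
        """Build design and model in one step; K must be indexed like cohort.

        Rows of ``cohort`` dropped for missing data are also dropped from K.
        """
        design = build_design(cohort, trait, traits=traits)
        if len(design.ids) != K.shape[0]:
            keep = [i for i, s in enumerate(cohort["id"]) if s in set(design.ids)]
            K = K[np.ix_(keep, keep)]
        return cls(design, K, **kwargs)

    def _start_values(self) -> np.ndarray:
        st = self._state
        vp = float(np.var(st.y - st.X @ np.linalg.lstsq(st.X, st.y, rcond=None)[0]))
        vp = max(vp, 1e-8)
        th = {"var_direct": 0.3 * vp, "cov_direct_social": 0.0,
              "var_social": 0.02 * vp, "var_litter": 0.05 * vp,
              "var_group": 0.05 * vp, "var_residual": 0.55 * vp}
        return np.array([th[nm] for nm in st.names])

    def fit(self, maxiter: int = 200, tol: float = 1e-8,
            verbose: bool = False) -> SocialGeneticResults:
        st = self._state
        vp = float(np.var(st.y))
        floor = 1e-10 * vp
        theta = st.project(self._start_values(), floor)
        ll, P, Py = st.loglik_terms(theta)
        if ll is None:
            raise SingularModelError("starting covariance matrix is not PD")
        history = [ll]
        converged = False
        n_stalled = 0
        it = 0
        for it in range(1, maxiter + 1):
            npar = len(theta)
            tr = np.empty(npar)
            quad = np.empty(npar)
            B = np.empty((st.n, npar))
            for k, A in enumerate(st.A):
                tr[k] = float(np.sum(P * A))   # tr(P A), A symmetric
                B[:, k] = A @ Py
                quad[k] = float(Py @ B[:, k])  # y'P A P y
            score = 0.5 * (quad - tr)
            PB = P @ B
            AI = 0.5 * (B.T @ PB)

            # active set: a variance pinned at its floor with a downhill
            # score stays at the floor and leaves the update, otherwise the
            # projected AI step keeps being backtracked to nothing
            at_floor = np.array(
                [nm != "cov_direct_social" and th <= floor * 1.0001
                 for nm, th in zip(st.names, theta)]
            )
            free = ~(at_floor & (score < 0))
            # a floored genetic variance pinches the covariance to ~0 through
            # the PSD bound; freeze the covariance too or it wobbles forever
            if st.estimate_cov and "var_social" in st.names:
                i_s = st.names.index("var_social")
                i_c = st.names.index("cov_direct_social")
                if not free[i_s] or theta[i_s] <= floor * 1.0001:
                    theta[i_c] = 0.0
                    free[i_c] = False
            if not free.any():
                break

            # AI step with Levenberg-style ridge and backtracking; the cheap
            # Cholesky-only likelihood screens candidates, the P-matrix form
            # is evaluated once for the accepted point
            new_theta, new_ll = None, None
            ridge = 0.0
            AIf = AI[np.ix_(free, free)]
            for _ in range(3):
                step = np.zeros(npar)
                try:
                    step[free] = np.linalg.solve(
                        AIf + ridge * np.eye(int(free.sum())), score[free])
                except np.linalg.LinAlgError:
                    ridge = max(10 * ridge, 1e-6 * np.trace(AIf) / npar)
                    continue
                frac = 1.0
                for _ in range(12):
                    cand = st.project(theta + frac * step, floor)
                    cll = st.loglik(cand)
                    if np.isfinite(cll) and cll >= ll - 1e-12:
                        new_theta, new_ll = cand, cll
                        break
                    frac *= 0.5
                if new_theta is not None:
                    break
                ridge = max(10 * ridge, 1e-6 * np.trace(AIf) / npar)
            if new_theta is None:
                # EM fallback: guaranteed-direction steps scaled by theta^2/dim
                em = theta + theta**2 * (quad - tr) / np.array(st.dims)
                frac = 1.0
                for _ in range(12):
                    cand = st.project(theta + frac * (em - theta), floor)
                    cll = st.loglik(cand)
                    if np.isfinite(cll) and cll >= ll - 1e-12:
                        new_theta, new_ll = cand, cll
                        break
                    frac *= 0.5
            if new_theta is None:
                # no admissible uphill step within tolerance: a constrained
                # (boundary) optimum up to numerical precision
                converged = it > 1
                break
            _, P, Py = st.loglik_terms(new_theta)

            delta = np.abs(new_theta - theta) / np.maximum(np.abs(theta), 1e-6 * vp)
            ll_gain = new_ll - ll
            theta, ll = new_theta, new_ll
            history.append(ll)
            if verbose:
                print(f"iter {it:3d}  loglik {ll:.8f}  max rel change {delta.max():.3e}")
            if delta.max() < tol:
                converged = True
                break
            if ll_gain < 1e-6:
                n_stalled += 1
                # flat likelihood over several iterations: the remaining
                # movement is a boundary crawl, treat as converged when the
                # parameters have stopped moving materially
                if n_stalled >= 5:
                    converged = delta.max() < 1e-2
                    break
            else:
                n_stalled = 0
            # geometric-decay crawls along the PSD boundary: a whole window
            # of iterations buying < 1e-4 log-likelihood is an optimum
            if it >= 10 and history[-1] - history[-11] < 1e-4 and delta.max() < 0.05:
                converged = True
                break

        varcomps = dict(zip(st.names, theta))
        if self.include_social and not self.estimate_cov_ds:
            varcomps["cov_direct_social"] = 0.0
        order = ["var_direct", "cov_direct_social", "var_social",
                 "var_litter", "var_group", "var_residual"]
        varcomps = {k: float(varcomps[k]) for k in order if k in varcomps}
        return SocialGeneticResults(
            model=self, varcomps=varcomps, loglik=float(ll),
            converged=converged, n_iter=it, loglik_history=history,
            n_bent_eigenvalues=self.n_bent,
        )

    # -- mixed-model equations ---------------------------------------------

    def _solve_mme(self, varcomps: dict[str, float]) -> dict[str, np.ndarray]:
        d = self.design
        n = d.y.shape[0]
        s2e = max(varcomps["var_residual"], 1e-12)
        Ki = np.linalg.inv(self.K)
        blocks = [d.Z_D]
        if self.include_social:
            blocks.append(d.Z_S)
        if self.include_litter:
            blocks.append(d.W)
        if self.include_group:
            blocks.append(d.V)
        Z = np.hstack(blocks)
        nK = self.K.shape[0]
        sizes = [nK] + ([nK] if self.include_social else []) \
            + ([d.W.shape[1]] if self.include_litter else []) \
            + ([d.V.shape[1]] if self.include_group else [])
        Gi_blocks: list[np.ndarray] = []
        if self.include_social:
            C = np.array(
                [[varcomps["var_direct"], varcomps.get("cov_direct_social", 0.0)],
                 [varcomps.get("cov_direct_social", 0.0), varcomps["var_social"]]]
            )
            # guard a boundary estimate
            w, Q = np.linalg.eigh(C)
            w = np.maximum(w, 1e-12 * max(np.trace(C), 1e-12))
            Ci = (Q / w) @ Q.T
            Gi_blocks.append(np.kron(Ci, Ki))
        else:
            Gi_blocks.append(Ki / max(varcomps["var_direct"], 1e-12))
        if self.include_litter:
            Gi_blocks.append(np.eye(d.W.shape[1]) / max(varcomps["var_litter"], 1e-12))
        if self.include_group:
            Gi_blocks.append(np.eye(d.V.shape[1]) / max(varcomps["var_group"], 1e-12))
        from scipy.linalg import block_diag

        Gi = block_diag(*Gi_blocks)
        X = d.X
        qf = X.shape[1]
        top = np.hstack([X.T @ X, X.T @ Z]) / s2e
        bot = np.hstack([Z.T @ X / s2e, Z.T @ Z / s2e + Gi])
        lhs = np.vstack([top, bot])
        rhs = np.concatenate([X.T @ d.y, Z.T @ d.y]) / s2e
        try:
            Cinv = np.linalg.inv(lhs)
        except np.linalg.LinAlgError as err:
            raise SingularModelError(
                "mixed-model equations are singular (confounded terms)"
            ) from err
        sol = Cinv @ rhs
        out: dict[str, np.ndarray] = {"b": sol[:qf]}
        offset = qf
        diag = np.diag(Cinv)
        out["a_D"] = sol[offset : offset + nK]
        out["pev_D"] = np.maximum(diag[offset : offset + nK], 0.0)
        offset += nK
        if self.include_social:
            out["a_S"] = sol[offset : offset + nK]
            out["pev_S"] = np.maximum(diag[offset : offset + nK], 0.0)
        return out


# ---------------------------------------------------------------------------
# Accuracy and deregression
# ---------------------------------------------------------------------------


def accuracy_from_pev(pev: np.ndarray | float, sigma2: float) -> np.ndarray | float:
    """EBV accuracy r = sqrt(1 - PEV / sigma2), clamped to 0 when PEV >= sigma2.

    ``sigma2`` is the genetic variance of the corresponding effect. Clamped
    entries indicate the EBV carries no information at the estimated variance.
    """
    if sigma2 <= 0:
        raise ValueError("genetic variance must be positive for an accuracy")
    pev_arr = np.asarray(pev, dtype=float)
    ratio = np.clip(1.0 - pev_arr / sigma2, 0.0, 1.0)
    r = np.sqrt(ratio)
    if np.ndim(pev) == 0:
        return float(r)
    return r


def deregress(ebv, r, r2_floor: float = 0.01):
    """Deregressed EBV g / r^2; below the r^2 floor the value is unusable (NaN)."""
    ebv_arr = np.asarray(ebv, dtype=float)
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr > 1)):
        raise ValueError("accuracy must lie in [0, 1]")
    r2 = r_arr**2
    out = np.where(r2 >= r2_floor, ebv_arr / np.where(r2 > 0, r2, np.nan), np.nan)
    if np.ndim(ebv) == 0:
        return float(out)
    return out


def reml_fit_social(design: DesignSet, K: np.ndarray, **kwargs) -> SocialGeneticResults:
    """Functional wrapper: fit the social model on a design and K."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("maxiter", "tol", "verbose")
                  if k in kwargs}
    return SocialGeneticModel(design, K, **kwargs).fit(**fit_kwargs)
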