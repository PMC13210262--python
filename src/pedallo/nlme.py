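"""Nonlinear mixed-effects estimation (FOCE with interaction) for the
one-compartment allometric PK model.

The marginal likelihood of each subject's data is approximated by a Laplace
expansion around the conditional mode of the random effects (the empirical
Bayes estimate), with the proportional residual variance evaluated at the
conditional prediction — the "interaction" part.  Writing

    h_i(eta) = sum_j [ ln(2*pi*g_ij^2) + (y_ij - f_ij)^2 / g_ij^2 ]
               + eta' Omega^-1 eta + ln|2*pi*Omega|,
    g_ij = sigma * |f_ij(eta)|,

the per-subject contribution to -2 log-likelihood is

    h_i(eta_hat) - q*ln(2*pi) + ln det(H_i / 2),   H_i = grad^2 h_i(eta_hat),

with q = 3 random effects.  The inner mode search is a damped Newton
iteration vectorized across subjects; the outer search maximizes the summed
approximation over a transformed parameter vector (log typical values, free
exponents, log random-effect SDs, atanh correlation, log sigma) with
L-BFGS-B.  Derivatives of h with respect to eta use central finite
differences batched into single vectorized model evaluations, so one outer
objective costs a handful of numpy calls regardless of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .pk import EtaVector, PKDataset, PopulationPKParams, _conc_arrays

__all__ = [
    "SubjectRecords",
    "EstimationSpec",
    "FitResult",
    "individual_neg2ll",
    "inner_ebe",
    "focei_objective",
    "fit_nlme",
]

_Q = 3  # number of random effects
_LOG2PI = float(np.log(2.0 * np.pi))

# central-difference stencil over eta: row 0 base, 1-3 +e_k, 4-6 -e_k,
# 7-18 the (+/-, +/-) corners for the pairs (0,1), (0,2), (1,2)
_PAIRS = [(0, 1), (0, 2), (1, 2)]
_STENCIL = np.zeros((19, _Q))
for _k in range(_Q):
    _STENCIL[1 + _k, _k] = 1.0
    _STENCIL[4 + _k, _k] = -1.0
for _p, (_i, _j) in enumerate(_PAIRS):
    for _s, (_si, _sj) in enumerate([(1, 1), (1, -1), (-1, 1), (-1, -1)]):
        _STENCIL[7 + 4 * _p + _s, _i] = _si
        _STENCIL[7 + 4 * _p + _s, _j] = _sj

_FD_STEP = 5e-4
_BIG = 1e10


@dataclass(frozen=True)
class SubjectRecords:
    """One subject's data as seen by the estimator."""

    dose_mg: float
    weight_kg: float
    times: np.ndarray
    dv: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.dv, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and dv must be equal-length nonempty vectors")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dv", y)


@dataclass(frozen=True)
class ThetaInit:
    """Initial values on the natural scale (deliberately away from any truth)."""

    tv_v: float = 10.0
    tv_cl: float = 0.7
    tv_ka: float = 0.5
    exp_v: float = 0.5
    exp_cl: float = 0.5
    sd_v: float = 0.3
    sd_cl: float = 0.3
    sd_ka: float = 0.3
    corr_v_cl: float = 0.0
    sigma_prop: float = 0.2


@dataclass
class EstimationSpec:
    """What to estimate, from where, and when to give up."""

    estimate_exp_v: bool = True
    estimate_exp_cl: bool = True
    fixed_exp_v: float = 1.0
    fixed_exp_cl: float = 0.75
    initial: ThetaInit = field(default_factory=ThetaInit)
    ref_weight: float = 70.0
    max_outer_iters: int = 300
    ftol: float = 1e-6          # relative objective change on the outer search
    gtol: float = 1e-3          # projected-gradient sup-norm, transformed scale
    max_retries: int = 3        # extra jittered restarts on failure
    n_starts: int = 1           # independent starts always run (best kept);
                                # >1 guards against local optima in degenerate
                                # (e.g. near-zero-variance) likelihoods
    jitter_scale: float = 0.2   # +/- on the transformed (log) scale
    jitter_seed: int = 0


@dataclass
class FitResult:
    """Point estimates plus diagnostics from one FOCEI fit."""

    estimates: dict
    ebes: np.ndarray            # (n_subjects, 3) conditional modes
    objective: float            # -2 x approximate log-likelihood
    converged: bool
    n_function_evals: int
    messages: list

    @property
    def exp_v(self) -> float:
        return self.estimates["exp_v"]

    @property
    def exp_cl(self) -> float:
        return self.estimates["exp_cl"]

    def as_population_params(self) -> PopulationPKParams:
        e = self.estimates
        to_cv = lambda sd: float(np.sqrt(np.expm1(sd**2)))
        return PopulationPKParams(
            tv_v=e["tv_v"], tv_cl=e["tv_cl"], tv_ka=e["tv_ka"],
            cv_v=to_cv(e["sd_v"]), cv_cl=to_cv(e["sd_cl"]), cv_ka=to_cv(e["sd_ka"]),
            corr_v_cl=e["corr_v_cl"], sigma_prop=e["sigma_prop"],
            exp_v=e["exp_v"], exp_cl=e["exp_cl"],
        )


# ---------------------------------------------------------------------------
# natural-scale parameter bundle used internally
# ---------------------------------------------------------------------------

@dataclass
class _NatParams:
    tv_v: float
    tv_cl: float
    tv_ka: float
    exp_v: float
    exp_cl: float
    sd_v: float
    sd_cl: float
    sd_ka: float
    corr: float
    sigma: float

    def omega(self) -> np.ndarray:
        om = np.diag([self.sd_v**2, self.sd_cl**2, self.sd_ka**2])
        om[0, 1] = om[1, 0] = self.corr * self.sd_v * self.sd_cl
        return om

    @classmethod
    def from_population(cls, pop: PopulationPKParams) -> "_NatParams":
        sd = pop.eta_sds()
        return cls(pop.tv_v, pop.tv_cl, pop.tv_ka, pop.exp_v, pop.exp_cl,
                   sd[0], sd[1], sd[2], pop.corr_v_cl, pop.sigma_prop)

    def as_dict(self) -> dict:
        return {
            "tv_v": self.tv_v, "tv_cl": self.tv_cl, "tv_ka": self.tv_ka,
            "exp_v": self.exp_v, "exp_cl": self.exp_cl,
            "sd_v": self.sd_v, "sd_cl": self.sd_cl, "sd_ka": self.sd_ka,
            "corr_v_cl": self.corr, "sigma_prop": self.sigma,
        }


class _FoceiProblem:
    """Vectorized FOCEI machinery for one dataset."""

    def __init__(self, dose, wt, T, Y, mask, ref_weight=70.0):
        self.dose = np.asarray(dose, float)
        self.wt = np.asarray(wt, float)
        self.T = np.asarray(T, float)
        self.Y = np.asarray(Y, float)
        self.mask = np.asarray(mask, bool)
        self.ref_weight = ref_weight
        self.n, self.m = self.T.shape
        self.warm = np.zeros((self.n, _Q))

    @classmethod
    def from_dataset(cls, dataset: PKDataset, ref_weight=70.0) -> "_FoceiProblem":
        dose, wt, T, Y, mask = dataset.subject_arrays()
        return cls(dose, wt, T, Y, mask, ref_weight)

    @classmethod
    def from_records(cls, records: Sequence[SubjectRecords], ref_weight=70.0):
        m = max(r.times.size for r in records)
        n = len(records)
        T = np.ones((n, m)); Y = np.ones((n, m)); mask = np.zeros((n, m), bool)
        for i, r in enumerate(records):
            T[i, : r.times.size] = r.times
            Y[i, : r.times.size] = r.dv
            mask[i, : r.times.size] = True
        return cls([r.dose_mg for r in records], [r.weight_kg for r in records],
                   T, Y, mask, ref_weight)

    # -- likelihood kernel --------------------------------------------------

    def _omega_terms(self, p: _NatParams):
        om = p.omega()
        sign, logdet = np.linalg.slogdet(om)
        if sign <= 0:
            return None, None
        return np.linalg.inv(om), float(logdet + _Q * _LOG2PI)

    def h(self, p: _NatParams, etas: np.ndarray, oinv: np.ndarray, logdet2pi: float,
          rows=None):
        """Joint -2 log-density; etas has shape (..., k, 3), returns (..., k).

        ``rows`` selects a subject subset (defaults to all subjects)."""
        if rows is None:
            wt, dose, T, Y, mask = self.wt, self.dose, self.T, self.Y, self.mask
        else:
            wt, dose, T, Y, mask = (self.wt[rows], self.dose[rows], self.T[rows],
                                    self.Y[rows], self.mask[rows])
        wr = wt / self.ref_weight
        with np.errstate(all="ignore"):
            v = p.tv_v * np.exp(etas[..., 0]) * wr**p.exp_v
            cl = p.tv_cl * np.exp(etas[..., 1]) * wr**p.exp_cl
            ka = p.tv_ka * np.exp(etas[..., 2])
            f = _conc_arrays(dose[:, None], v[..., None], cl[..., None], ka[..., None], T)
            g2 = (p.sigma * f) ** 2
            data = np.where(mask, (Y - f) ** 2 / g2 + np.log(2 * np.pi * g2), 0.0)
            quad = np.einsum("...i,ij,...j->...", etas, oinv, etas)
            out = data.sum(axis=-1) + quad + logdet2pi
        return np.where(np.isfinite(out), out, _BIG)

    def _derivs(self, p, eta, oinv, logdet2pi, rows=None):
        """Value, gradient and Hessian of h wrt eta, analytic.

        With u = y/f the data term is sum_j [2 ln f_j + (u_j-1)^2/sigma^2]
        plus constants, so per observation

            grad_k contribution = A_j * d_jk,
            Hess_kl contribution = A_j * e_jkl + B_j * d_jk * d_jl,
            A_j = 2 (1 - (u^2-u)/sigma^2),  B_j = (2/sigma^2) (2u-1) u,

        where d and e are first/second derivatives of ln f with respect to
        eta, obtained by chaining through ke = CL/V and ka.  Rows where
        ka ~ ke (removable singularity of the closed form) fall back to the
        finite-difference stencil."""
        if rows is None:
            wt, dose, T, Y, mask = self.wt, self.dose, self.T, self.Y, self.mask
            nrows = np.arange(self.n)
        else:
            wt, dose, T, Y, mask = (self.wt[rows], self.dose[rows], self.T[rows],
                                    self.Y[rows], self.mask[rows])
            nrows = rows
        k = eta.shape[0]
        with np.errstate(all="ignore"):
            wr = wt / self.ref_weight
            v = p.tv_v * np.exp(eta[:, 0]) * wr**p.exp_v
            cl = p.tv_cl * np.exp(eta[:, 1]) * wr**p.exp_cl
            ka = p.tv_ka * np.exp(eta[:, 2])
            ke = cl / v
            dk = ka - ke
            deg = np.abs(dk) < 1e-6 * np.maximum(ka, ke)
            E1 = np.exp(-ke[:, None] * T)
            E2 = np.exp(-ka[:, None] * T)
            S = E1 - E2
            f = dose[:, None] * ka[:, None] / (v[:, None] * dk[:, None]) * S
            sig2 = p.sigma**2
            u = Y / f
            hdata = np.where(mask, (Y - f) ** 2 / (sig2 * f * f)
                             + np.log(2 * np.pi * sig2 * f * f), 0.0)
            quad = np.einsum("ki,ij,kj->k", eta, oinv, eta)
            h0 = hdata.sum(axis=-1) + quad + logdet2pi

            A = np.where(mask, 2.0 * (1.0 - (u * u - u) / sig2), 0.0)
            B = np.where(mask, (2.0 / sig2) * (2.0 * u - 1.0) * u, 0.0)
            invdk = 1.0 / dk[:, None]
            C = T * T * E1 * E2 / (S * S)
            Lke = invdk - T * E1 / S
            Lka = 1.0 / ka[:, None] - invdk + T * E2 / S
            Mkk = invdk * invdk - C
            Mka = -invdk * invdk + C
            Maa = -1.0 / ka[:, None] ** 2 + invdk * invdk - C
            kem = ke[:, None]
            kam = ka[:, None]
            d_a = -1.0 - kem * Lke
            d_b = kem * Lke
            d_c = kam * Lka
            e_aa = kem * Lke + kem * kem * Mkk
            e_ac = -kem * kam * Mka
            e_cc = kam * Lka + kam * kam * Maa
            dlist = (d_a, d_b, d_c)
            emap = {(0, 0): e_aa, (0, 1): -e_aa, (1, 1): e_aa,
                    (0, 2): e_ac, (1, 2): -e_ac, (2, 2): e_cc}
            g = np.stack([(A * d).sum(axis=-1) for d in dlist], axis=-1) + 2.0 * eta @ oinv
            H = np.empty((k, _Q, _Q))
            for i in range(_Q):
                for j in range(i, _Q):
                    Hij = (A * emap[(i, j)] + B * dlist[i] * dlist[j]).sum(axis=-1)
                    H[:, i, j] = H[:, j, i] = Hij
            H += 2.0 * oinv

        h0 = np.where(np.isfinite(h0), h0, _BIG)
        bad = (deg | ~np.isfinite(g).all(axis=1)
               | ~np.isfinite(H.reshape(k, -1)).all(axis=1))
        if bad.any():
            hb, gb, Hb = self._derivs_fd(p, eta[bad], oinv, logdet2pi, rows=nrows[bad])
            h0[bad], g[bad], H[bad] = hb, gb, Hb
        return h0, g, H

    def _derivs_fd(self, p, eta, oinv, logdet2pi, rows=None, s=_FD_STEP):
        """Finite-difference fallback for _derivs (degenerate ka ~ ke rows)."""
        k = eta.shape[0]
        pts = eta[None, :, :] + s * _STENCIL[:, None, :]
        hv = self.h(p, pts, oinv, logdet2pi, rows=rows)   # (19, k)
        h0 = hv[0]
        # diverged subjects (h capped at _BIG) produce garbage derivatives here;
        # the caller restarts them, so just keep the arithmetic quiet
        with np.errstate(all="ignore"):
            g = ((hv[1:4] - hv[4:7]) / (2 * s)).T         # (k, 3)
            H = np.empty((k, _Q, _Q))
            for d in range(_Q):
                H[:, d, d] = (hv[1 + d] + hv[4 + d] - 2 * h0) / s**2
            for pi, (i, j) in enumerate(_PAIRS):
                base = 7 + 4 * pi
                hij = (hv[base] - hv[base + 1] - hv[base + 2] + hv[base + 3]) / (4 * s**2)
                H[:, i, j] = H[:, j, i] = hij
        return h0, g, H

    def inner(self, p: _NatParams, eta0, oinv, logdet2pi, gtol=1e-5, max_iter=40):
        """Damped-Newton conditional-mode search, vectorized across subjects.

        Iterates only on the shrinking set of unconverged subjects.
        Returns (eta_hat, h_hat, H_hat, ok)."""
        n = self.n
        eta = eta0.copy()
        h_all = np.empty(n)
        H_all = np.empty((n, _Q, _Q))
        g_all = np.empty((n, _Q))
        lam = np.zeros(n)
        eye = np.eye(_Q)
        idx = np.arange(n)  # unconverged subjects
        restarted = np.zeros(n, bool)
        for _ in range(max_iter):
            h0, g, H = self._derivs(p, eta[idx], oinv, logdet2pi, rows=idx)
            h_all[idx], g_all[idx], H_all[idx] = h0, g, H
            # restart diverged subjects once at the prior mode
            bad = (h0 >= _BIG) & ~restarted[idx]
            if bad.any():
                eta[idx[bad]] = 0.0
                restarted[idx[bad]] = True
                continue
            if np.any(h0 >= _BIG):
                return eta, h_all, H_all, False
            gnorm = np.abs(g).max(axis=1)
            live = gnorm > gtol
            if not live.any():
                return eta, h_all, H_all, True
            idx = idx[live]
            h0, g, H = h0[live], g[live], H[live]
            k = idx.size
            Hd = H + (lam[idx, None, None] + 1e-12) * eye
            try:
                step = np.linalg.solve(Hd, -g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                Hd = H + (lam[idx, None, None] + 1.0) * eye
                step = np.linalg.solve(Hd, -g[..., None])[..., 0]
            # fall back to steepest descent where not a descent direction
            not_desc = np.einsum("ij,ij->i", g, step) >= 0
            step[not_desc] = -g[not_desc]
            alpha = np.ones(k)
            improved = np.zeros(k, bool)
            sub = np.arange(k)  # positions still line-searching
            for _ls in range(5):
                cand = eta[idx[sub]] + alpha[sub, None] * step[sub]
                hc = self.h(p, cand, oinv, logdet2pi, rows=idx[sub])
                ok = hc < h0[sub] - 1e-13
                eta[idx[sub[ok]]] = cand[ok]
                improved[sub[ok]] = True
                sub = sub[~ok]
                if sub.size == 0:
                    break
                alpha[sub] *= 0.5
            lam[idx[improved]] *= 0.3
            stuck = idx[~improved]
            lam[stuck] = np.maximum(lam[stuck] * 10.0, 1e-2)
            # a subject that cannot improve at a small gradient is at its mode
            done_enough = ~improved & (np.abs(g).max(axis=1) < 1e-3)
            idx = idx[~done_enough]
            if idx.size == 0:
                return eta, h_all, H_all, True
        h0, g, H = self._derivs(p, eta[idx], oinv, logdet2pi, rows=idx)
        h_all[idx], g_all[idx], H_all[idx] = h0, g, H
        return eta, h_all, H_all, bool(np.abs(g_all).max() < 1e-2)

    def objective(self, p: _NatParams, warm: bool = True) -> float:
        """FOCE-with-interaction -2 log-likelihood of the whole dataset.

        Hopeless parameter regions (overshooting line-search probes) return a
        large finite value with a slope back toward sanity instead of a flat
        ceiling, so the outer optimizer can always recover."""
        if min(p.tv_v, p.tv_cl, p.tv_ka, p.sd_v, p.sd_cl, p.sd_ka, p.sigma) <= 0:
            return _BIG
        res = self._omega_terms(p)
        if res[0] is None:
            return _BIG
        oinv, logdet2pi = res
        zeros = np.zeros((self.n, _Q))
        h_far = self.h(p, zeros, oinv, logdet2pi)
        if not np.all(np.isfinite(h_far)) or np.any(h_far >= _BIG):
            return _BIG
        far = float(h_far.sum())
        if far > 1e8:  # far field: the joint density at eta=0 is guidance enough
            return min(far, 1e15)
        eta0 = self.warm if warm else zeros
        eta, h0, H, ok = self.inner(p, eta0, oinv, logdet2pi)
        if warm and (not ok or np.any(h0 >= _BIG)):
            eta, h0, H, ok = self.inner(p, zeros, oinv, logdet2pi)
        if not np.all(np.isfinite(h0)) or np.any(h0 >= _BIG):
            return _BIG
        # Laplace curvature, clamped to positive definite (a converged mode
        # has PSD curvature; tiny negative eigenvalues are numerical)
        evals = np.linalg.eigvalsh(H / 2.0)
        logdet = np.log(np.maximum(evals, 1e-8)).sum(axis=1)
        if ok:
            self.warm = eta
        val = float(np.sum(h0) - _Q * _LOG2PI * self.n + np.sum(logdet))
        return val if np.isfinite(val) else _BIG


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def individual_neg2ll(
    theta: PopulationPKParams, eta: EtaVector, records: SubjectRecords
) -> float:
    """Joint -2 log-density of one subject's data and random effects."""
    prob = _FoceiProblem.from_records([records], ref_weight=theta.ref_weight)
    p = _NatParams.from_population(theta)
    oinv, logdet2pi = prob._omega_terms(p)
    if oinv is None:
        raise ValueError("random-effect covariance is singular")
    return float(prob.h(p, eta.as_array()[None, :], oinv, logdet2pi)[0])


def inner_ebe(
    theta: PopulationPKParams,
    records: SubjectRecords,
    start_eta: EtaVector | None = None,
) -> EtaVector:
    """Empirical Bayes estimate: conditional mode of one subject's etas."""
    prob = _FoceiProblem.from_records([records], ref_weight=theta.ref_weight)
    p = _NatParams.from_population(theta)
    oinv, logdet2pi = prob._omega_terms(p)
    if oinv is None:
        raise ValueError("random-effect covariance is singular")
    eta0 = (start_eta or EtaVector()).as_array()[None, :]
    eta, _, _, ok = prob.inner(p, eta0, oinv, logdet2pi)
    if not ok:
        raise RuntimeError("conditional-mode search did not converge")
    return EtaVector(*eta[0])


def focei_objective(theta: PopulationPKParams, dataset: PKDataset) -> float:
    """FOCEI -2 log-likelihood of a dataset at fixed population parameters."""
    prob = _FoceiProblem.from_dataset(dataset, ref_weight=theta.ref_weight)
    return prob.objective(_NatParams.from_population(theta), warm=False)


def _pack(init: ThetaInit, spec: EstimationSpec) -> tuple[np.ndarray, list]:
    names = ["ltv_v", "ltv_cl", "ltv_ka"]
    x = [np.log(init.tv_v), np.log(init.tv_cl), np.log(init.tv_ka)]
    if spec.estimate_exp_v:
        names.append("exp_v"); x.append(init.exp_v)
    if spec.estimate_exp_cl:
        names.append("exp_cl"); x.append(init.exp_cl)
    names += ["lsd_v", "lsd_cl", "lsd_ka", "zcorr", "lsigma"]
    x += [np.log(init.sd_v), np.log(init.sd_cl), np.log(init.sd_ka),
          np.arctanh(init.corr_v_cl), np.log(init.sigma_prop)]
    return np.array(x), names


def _unpack(x: np.ndarray, names: list, spec: EstimationSpec) -> _NatParams:
    d = dict(zip(names, x))
    return _NatParams(
        tv_v=np.exp(d["ltv_v"]), tv_cl=np.exp(d["ltv_cl"]), tv_ka=np.exp(d["ltv_ka"]),
        exp_v=d.get("exp_v", spec.fixed_exp_v),
        exp_cl=d.get("exp_cl", spec.fixed_exp_cl),
        sd_v=np.exp(d["lsd_v"]), sd_cl=np.exp(d["lsd_cl"]), sd_ka=np.exp(d["lsd_ka"]),
        corr=np.tanh(d["zcorr"]), sigma=np.exp(d["lsigma"]),
    )


def _bounds(names: list) -> list:
    b = {
        "ltv_v": (np.log(1e-2), np.log(1e4)),
        "ltv_cl": (np.log(1e-4), np.log(1e3)),
        "ltv_ka": (np.log(1e-3), np.log(1e3)),
        "exp_v": (-3.0, 5.0),
        "exp_cl": (-3.0, 5.0),
        "lsd_v": (np.log(1e-3), np.log(5.0)),
        "lsd_cl": (np.log(1e-3), np.log(5.0)),
        "lsd_ka": (np.log(1e-3), np.log(5.0)),
        "zcorr": (-6.0, 6.0),
        "lsigma": (np.log(1e-3), np.log(5.0)),
    }
    return [b[name] for name in names]


def fit_nlme(dataset: PKDataset, spec: EstimationSpec | None = None) -> FitResult:
    """Maximize the FOCEI approximate likelihood over the transformed
    parameter vector; retries with jittered initial values on failure.

    Never raises on non-convergence: the returned ``FitResult`` carries
    ``converged=False`` and the caller decides inclusion.
    """
    spec = spec or EstimationSpec()
    prob = _FoceiProblem.from_dataset(dataset, ref_weight=spec.ref_weight)
    x0, names = _pack(spec.initial, spec)
    bounds = _bounds(names)
    jitter_rng = np.random.default_rng(spec.jitter_seed)

    messages: list[str] = []
    nfev = 0
    best = None
    n_ok = 0
    for attempt in range(spec.n_starts + spec.max_retries):
        x_start = x0 if attempt == 0 else x0 + jitter_rng.uniform(
            -spec.jitter_scale, spec.jitter_scale, size=x0.size)
        prob.warm = np.zeros((prob.n, _Q))

        def fun(x):
            return prob.objective(_unpack(x, names, spec))

        # central-difference outer gradients: forward differences are too
        # biased in the sharp likelihood valleys of low-variance fits
        res = minimize(
            fun, x_start, method="L-BFGS-B", bounds=bounds, jac="3-point",
            options=dict(maxiter=spec.max_outer_iters, maxfun=40000,
                         ftol=spec.ftol, gtol=spec.gtol),
        )
        nfev += res.nfev
        messages.append(f"attempt {attempt}: {res.message} (obj={res.fun:.6g})")
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun < _BIG / 2
        n_ok += ok
        if best is None or (ok and not best[1]) or (
            ok == best[1] and np.isfinite(res.fun) and res.fun < best[0].fun
        ):
            best = (res, ok)
        if n_ok >= spec.n_starts:
            break

    res, converged = best
    p_hat = _unpack(res.x, names, spec)
    # refresh EBEs at the returned optimum
    final_obj = prob.objective(p_hat, warm=True)
    return FitResult(
        estimates=p_hat.as_dict(),
        ebes=prob.warm.copy(),
        objective=float(final_obj),
        converged=converged and np.isfinite(final_obj) and final_obj < _BIG / 2,
        n_function_evals=nfev,
        messages=messages,
    )
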