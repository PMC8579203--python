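"""Panel-observed 3-state continuous-time Markov model of health needs.

States are LOW_NEEDS (0) and HIGH_NEEDS (1) with transitions permitted in
both directions, and an absorbing DEATH state (2) reachable from either
living state.  The process is observed intermittently: living states are
seen only at interview times (the interval-censored "panel" scheme), death
times are known exactly, and some contacts confirm survival without
revealing the needs state (censored-alive observations).

Transition intensities follow a log-linear (proportional-hazards) model,

    q_rs(z) = q0_rs * exp(beta_rs' z),

with covariates held piecewise-constant at their value at the start of each
observation interval.  Exponentiated coefficients are hazard ratios on the
corresponding instantaneous transition risk.

The likelihood of an interval from observed state r to

* an observed living state s is ``P_rs(dt; z)``,
* an exactly observed death is ``sum_k P_rk(dt; z) q_k,death(z)``,
* a terminal censored-alive contact is ``sum_k P_rk(dt; z)``,

where ``P(t) = expm(Q t)``.  Because death is absorbing, the living-states
block of ``P`` is the exponential of the 2x2 living sub-generator, which
this module evaluates in closed form (real eigenvalues are guaranteed for
this sign structure); intermediate censored-alive contacts marginalize out
exactly by the semigroup property and are merged into their surrounding
interval when covariates allow.

The public surface follows the Model/Results convention:
``MarkovPanelModel(data).fit()`` returns a :class:`MarkovPanelResults`
with estimates, standard errors, hazard-ratio tables and ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .segmentation import HealthState

logger = logging.getLogger(__name__)

__all__ = [
    "LOW", "HIGH", "DEATH", "CENSORED", "TRANSITIONS", "TRANSITION_LABELS",
    "PanelDataset", "IntensityModel", "build_panel",
    "generator_matrix", "transition_probability", "panel_log_likelihood",
    "MarkovPanelModel", "MarkovPanelResults", "fit_ctmc",
]

LOW, HIGH, DEATH = 0, 1, 2
CENSORED = -1

#: Allowed instantaneous transitions, in parameter order.
TRANSITIONS: tuple[tuple[int, int], ...] = ((LOW, HIGH), (HIGH, LOW), (LOW, DEATH), (HIGH, DEATH))
TRANSITION_LABELS = ("low->high", "high->low", "low->death", "high->death")

_STATE_CODES = {
    HealthState.LOW_NEEDS.value: LOW,
    HealthState.HIGH_NEEDS.value: HIGH,
    HealthState.DEATH.value: DEATH,
    HealthState.CENSORED.value: CENSORED,
}


class DataError(ValueError):
    """Raised for structurally invalid panel data."""


# ---------------------------------------------------------------------------
# containers

@dataclass
class PersonRecords:
    person_id: object
    times: np.ndarray          # (n,) strictly increasing, years
    states: np.ndarray         # (n,) codes LOW/HIGH/DEATH/CENSORED
    z: np.ndarray              # (n, k) covariates at each record


@dataclass
class PanelDataset:
    """Time-ordered observation sequences for the transition model."""

    persons: list[PersonRecords]
    covariate_names: tuple[str, ...]

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_records(self) -> int:
        return sum(len(p.times) for p in self.persons)


@dataclass
class IntensityModel:
    """Fitted (or hypothesised) intensities of the 3-state model.

    ``baseline_log_q[i]`` is log q0 for ``TRANSITIONS[i]``; ``beta[j, i]``
    is the log hazard ratio of covariate j on transition i.
    """

    baseline_log_q: np.ndarray               # (4,)
    beta: np.ndarray                         # (k, 4)
    covariate_names: tuple[str, ...] = ()
    cov_params: np.ndarray | None = None     # covariance of packed params
    converged: bool | None = None
    loglike: float | None = None

    @property
    def params(self) -> np.ndarray:
        return _pack(self.baseline_log_q, self.beta)

    def intensities(self, z=None) -> np.ndarray:
        """Vector of the four allowed intensities at covariates ``z``."""
        z = np.zeros(self.beta.shape[0]) if z is None else np.asarray(z, float)
        return np.exp(self.baseline_log_q + z @ self.beta)


def _pack(log_q0: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return np.concatenate([np.asarray(log_q0, float).ravel(),
                           np.asarray(beta, float).ravel()])


def _unpack(params: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    params = np.asarray(params, float)
    return params[:4], params[4:].reshape(k, 4)


# ---------------------------------------------------------------------------
# generator algebra

def generator_matrix(model: IntensityModel, z=None) -> np.ndarray:
    """3x3 generator Q at covariate vector ``z``.

    Off-diagonals on allowed transitions are ``q0 exp(beta'z)``; the DEATH
    row is zero (absorbing) and diagonals make each row sum to zero.
    """
    q = model.intensities(z)
    if not np.all(np.isfinite(q)):
        raise FloatingPointError("non-finite transition intensity")
    Q = np.zeros((3, 3))
    for (r, s), qi in zip(TRANSITIONS, q):
        Q[r, s] = qi
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(3)] = -Q.sum(axis=1)
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Interval transition probability matrix P(t) = expm(Q t)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    Q = np.asarray(Q, float)
    P = expm(Q * t)
    return np.clip(P, 0.0, 1.0)


def _living_propagator(A: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """expm(A*dt) for the 2x2 living-states sub-generator, vectorized.

    A = [[-(q01+q02), q01], [q10, -(q10+q12)]] has discriminant
    (A00-A11)^2 + 4 q01 q10 >= 0, so eigenvalues are real; the spectral
    closed form is used, with a series fallback for (near-)coincident
    eigenvalues.
    """
    dts = np.asarray(dts, float)
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    disc = max(tr * tr - 4.0 * det, 0.0)
    s = np.sqrt(disc)
    I2 = np.eye(2)
    if s > 1e-12 * max(1.0, abs(tr)):
        l1, l2 = 0.5 * (tr + s), 0.5 * (tr - s)
        M1 = (A - l2 * I2) / (l1 - l2)
        M2 = I2 - M1
        P = (np.exp(l1 * dts)[:, None, None] * M1
             + np.exp(l2 * dts)[:, None, None] * M2)
    else:
        lam = 0.5 * tr
        N = A - lam * I2
        P = np.exp(lam * dts)[:, None, None] * (I2 + dts[:, None, None] * N)
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# panel construction

def build_panel(
    segmented: pd.DataFrame,
    covariates=(),
    person_col: str = "person_id",
    time_col: str = "interview_time",
    state_col: str = "health_state",
    death_time_col: str = "death_time",
    death_interval_end_col: str | None = None,
) -> PanelDataset:
    """Assemble a :class:`PanelDataset` from a segmented longitudinal table.

    Living/censored records are emitted at interview times.  For deceased
    persons a DEATH record is appended at ``death_time`` (exact death).
    When ``death_interval_end_col`` is given and the exact date is missing,
    the death is placed at the midpoint between the last contact and the
    interval end — a documented approximation for interval-known deaths.
    Covariate values attach to each record and act on the interval that
    starts there.
    """
    covariates = tuple(covariates)
    df = segmented.sort_values([person_col, time_col], kind="mergesort")
    pid_codes, pid_index = pd.factorize(df[person_col])
    all_times = df[time_col].to_numpy(float)
    all_states = df[state_col].map(_STATE_CODES).to_numpy(int)
    all_z = (df[list(covariates)].to_numpy(float)
             if covariates else np.zeros((len(df), 0)))
    if death_time_col in df.columns:
        all_death = df[death_time_col].to_numpy(float)
    else:
        all_death = np.full(len(df), np.nan)
    all_dend = (df[death_interval_end_col].to_numpy(float)
                if death_interval_end_col and death_interval_end_col in df.columns
                else None)
    bounds = np.flatnonzero(np.diff(pid_codes)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [len(df)]])

    persons: list[PersonRecords] = []
    n_dropped_leading = 0
    for a, b in zip(starts, stops):
        pid = pid_index[pid_codes[a]]
        times = all_times[a:b]
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise DataError(f"person {pid}: interview times not strictly increasing")
        states = all_states[a:b]
        z = all_z[a:b]

        if np.any(states == DEATH):
            # keep only records before the (single) death row
            first_death = int(np.argmax(states == DEATH))
            if np.any(states[first_death + 1:] != DEATH):
                raise DataError(f"person {pid}: observations after death")
            times, states, z = times[: first_death + 1], states[: first_death + 1], z[: first_death + 1]
        else:
            death = all_death[a:b]
            finite = death[np.isfinite(death)]
            dt_val = float(finite[0]) if len(finite) else np.nan
            if all_dend is not None and not np.isfinite(dt_val):
                dend = all_dend[a:b]
                dend = dend[np.isfinite(dend)]
                if len(dend):
                    dt_val = 0.5 * (times[-1] + float(dend[0]))
            if np.isfinite(dt_val):
                if dt_val <= times[-1]:
                    raise DataError(
                        f"person {pid}: death at {dt_val} not after last observation {times[-1]}"
                    )
                times = np.append(times, dt_val)
                states = np.append(states, DEATH)
                z = np.vstack([z, z[-1]]) if z.shape[1] else np.zeros((len(times), 0))

        # leading censored contacts carry no transition information
        start = 0
        while start < len(states) and states[start] == CENSORED:
            start += 1
            n_dropped_leading += 1
        times, states, z = times[start:], states[start:], z[start:]
        if len(states) == 0 or states[0] == DEATH:
            continue
        persons.append(PersonRecords(pid, times, states, z))
    if n_dropped_leading:
        logger.info("dropped %d leading censored records", n_dropped_leading)
    return PanelDataset(persons, covariates)


# ---------------------------------------------------------------------------
# likelihood preprocessing

@dataclass
class _PatternData:
    """Interval contributions sharing one covariate pattern."""

    panel_dts: np.ndarray = field(default_factory=lambda: np.empty(0))
    panel_counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 2, 2)))
    death_dts: np.ndarray = field(default_factory=lambda: np.empty(0))
    death_from: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    cens_dts: np.ndarray = field(default_factory=lambda: np.empty(0))
    cens_from: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    cens_counts: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class _Chain:
    """A contribution whose interval spans covariate changes: a product of
    living-block propagators followed by a terminal observation."""

    start_state: int
    pieces: list  # [(pattern_idx, dt), ...]
    kind: str     # "panel" | "death" | "censored"
    to_state: int | None


class MarkovPanelModel:
    """Maximum-likelihood CTMC model for panel-observed health states.

    Parameters
    ----------
    data : PanelDataset
        Output of :func:`build_panel`.
    constrain_beta : sequence of (covariate, transition_label) or None
        Optionally restrict covariate effects to a subset of transitions;
        by default every covariate acts on all four transitions.
    """

    def __init__(self, data: PanelDataset, constrain_beta=None):
        self.data = data
        self.covariate_names = data.covariate_names
        self.k = len(self.covariate_names)
        self.nparams = 4 + 4 * self.k
        self._free_beta = self._beta_mask(constrain_beta)
        self._preprocess()

    def _beta_mask(self, constrain) -> np.ndarray:
        mask = np.ones((self.k, 4), bool)
        if constrain is not None:
            mask[:] = False
            for cov, label in constrain:
                mask[self.covariate_names.index(cov), TRANSITION_LABELS.index(label)] = True
        return mask

    # -- preprocessing -----------------------------------------------------

    def _preprocess(self) -> None:
        zs = [p.z for p in self.data.persons if len(p.z)]
        allz = np.vstack(zs) if zs else np.zeros((0, 0))
        if allz.size:
            self.patterns, inverse = np.unique(allz, axis=0, return_inverse=True)
        else:
            self.patterns = np.zeros((1, self.k))
            inverse = None
        pat_of: dict[int, np.ndarray] = {}
        pos = 0
        for i, p in enumerate(self.data.persons):
            n = len(p.z)
            if inverse is None:
                pat_of[i] = np.zeros(n, int)
            else:
                pat_of[i] = inverse[pos: pos + n]
                pos += n

        panel_acc: dict[tuple[int, float], np.ndarray] = {}
        death_acc: dict[int, list] = {}
        cens_acc: dict[tuple[int, float, int], float] = {}
        chains: list[_Chain] = []
        self._crude_events = np.zeros(4)
        self._crude_exposure = np.zeros(2)

        for i, p in enumerate(self.data.persons):
            pats = pat_of[i]
            anchor = 0  # index of last concretely observed living state
            pieces: list[tuple[int, float]] = []
            for j in range(1, len(p.times)):
                dt = float(p.times[j] - p.times[j - 1])
                pat = int(pats[j - 1])
                if pieces and pieces[-1][0] == pat:
                    pieces[-1] = (pat, pieces[-1][1] + dt)  # semigroup merge
                else:
                    pieces.append((pat, dt))
                state = int(p.states[j])
                last = j == len(p.times) - 1
                if state == CENSORED and not last:
                    continue  # marginalized through exactly
                r = int(p.states[anchor])
                total_dt = sum(d for _, d in pieces)
                self._crude_exposure[r] += total_dt
                if state in (LOW, HIGH):
                    if state != r:
                        self._crude_events[TRANSITIONS.index((r, state))] += 1
                    if len(pieces) == 1:
                        key = (pieces[0][0], pieces[0][1])
                        C = panel_acc.setdefault(key, np.zeros((2, 2)))
                        C[r, state] += 1
                    else:
                        chains.append(_Chain(r, list(pieces), "panel", state))
                    anchor, pieces = j, []
                elif state == DEATH:
                    self._crude_events[TRANSITIONS.index((r, DEATH))] += 1
                    if len(pieces) == 1:
                        death_acc.setdefault(pieces[0][0], []).append((pieces[0][1], r))
                    else:
                        chains.append(_Chain(r, list(pieces), "death", None))
                else:  # terminal censored-alive contact
                    if len(pieces) == 1:
                        key = (pieces[0][0], pieces[0][1], r)
                        cens_acc[key] = cens_acc.get(key, 0.0) + 1.0
                    else:
                        chains.append(_Chain(r, list(pieces), "censored", None))

        self._per_pattern: list[_PatternData] = [
            _PatternData() for _ in range(len(self.patterns))
        ]
        for (pat, dt), C in panel_acc.items():
            pd_ = self._per_pattern[pat]
            pd_.panel_dts = np.append(pd_.panel_dts, dt)
            pd_.panel_counts = np.concatenate([pd_.panel_counts, C[None]], axis=0)
        for pat, items in death_acc.items():
            pd_ = self._per_pattern[pat]
            pd_.death_dts = np.array([d for d, _ in items])
            pd_.death_from = np.array([r for _, r in items], int)
        for (pat, dt, r), c in cens_acc.items():
            pd_ = self._per_pattern[pat]
            pd_.cens_dts = np.append(pd_.cens_dts, dt)
            pd_.cens_from = np.append(pd_.cens_from, r)
            pd_.cens_counts = np.append(pd_.cens_counts, c)
        self._chains = chains

    # -- likelihood --------------------------------------------------------

    def _pattern_matrices(self, params):
        log_q0, beta = _unpack(params, self.k)
        beta = np.where(self._free_beta, beta, 0.0)
        log_q = log_q0[None, :] + self.patterns @ beta  # (m, 4)
        q = np.exp(log_q)
        out = []
        for qp in q:
            A = np.array([[-(qp[0] + qp[2]), qp[0]],
                          [qp[1], -(qp[1] + qp[3])]])
            qd = np.array([qp[2], qp[3]])
            out.append((A, qd))
        return out

    def loglike(self, params) -> float:
        """Log-likelihood of the panel data at packed ``params``."""
        params = np.asarray(params, float)
        # -inf log-intensities encode structural zeros and are permitted
        if np.any(np.isnan(params)) or np.any(params == np.inf):
            return -np.inf
        mats = self._pattern_matrices(params)
        total = 0.0
        tiny = 1e-300
        for pat_idx, pdta in enumerate(self._per_pattern):
            A, qd = mats[pat_idx]
            if len(pdta.panel_dts):
                P = _living_propagator(A, pdta.panel_dts)
                C = pdta.panel_counts
                with np.errstate(divide="ignore"):
                    logP = np.log(np.maximum(P, tiny))
                total += float(np.sum(np.where(C > 0, C * logP, 0.0)))
            if len(pdta.death_dts):
                P = _living_propagator(A, pdta.death_dts)
                idx = np.arange(len(pdta.death_dts))
                prob = P[idx, pdta.death_from, 0] * qd[0] + P[idx, pdta.death_from, 1] * qd[1]
                total += float(np.sum(np.log(np.maximum(prob, tiny))))
            if len(pdta.cens_dts):
                P = _living_propagator(A, pdta.cens_dts)
                idx = np.arange(len(pdta.cens_dts))
                prob = P[idx, pdta.cens_from, 0] + P[idx, pdta.cens_from, 1]
                total += float(np.sum(pdta.cens_counts * np.log(np.maximum(prob, tiny))))
        for ch in self._chains:
            alpha = np.zeros(2)
            alpha[ch.start_state] = 1.0
            for pat_idx, dt in ch.pieces:
                A, qd = mats[pat_idx]
                alpha = alpha @ _living_propagator(A, np.array([dt]))[0]
            if ch.kind == "panel":
                prob = alpha[ch.to_state]
            elif ch.kind == "death":
                _, qd = mats[ch.pieces[-1][0]]
                prob = float(alpha @ qd)
            else:
                prob = float(alpha.sum())
            total += float(np.log(max(prob, tiny)))
        return total

    # -- fitting -----------------------------------------------------------

    def start_params(self) -> np.ndarray:
        """Crude-rate initial values: log(events / person-time at risk) per
        transition (floored at half an event), zero covariate effects."""
        q0 = np.empty(4)
        for i, (r, _) in enumerate(TRANSITIONS):
            T = max(self._crude_exposure[r], 1e-8)
            q0[i] = max(self._crude_events[i], 0.5) / T
        return _pack(np.log(q0), np.zeros((self.k, 4)))

    def fit(
        self,
        start_params=None,
        method: str = "BFGS",
        maxiter: int = 500,
        gtol: float = 1e-6,
        compute_cov: bool = True,
    ) -> "MarkovPanelResults":
        """Maximize the panel likelihood by quasi-Newton iteration.

        Gradients are finite-difference; the parameter covariance is the
        inverse observed information (numerical Hessian at the optimum).
        Non-identifiable transitions (no observed events) are flagged.
        """
        for i, label in enumerate(TRANSITION_LABELS):
            if self._crude_events[i] == 0:
                logger.warning("no observed %s transitions: baseline weakly identified", label)
        x0 = np.asarray(start_params, float) if start_params is not None else self.start_params()

        # fix betas excluded by the constraint mask at 0 via a reduced vector
        free = np.concatenate([np.ones(4, bool), self._free_beta.ravel()])
        full0 = x0.copy()

        def expand(xr):
            x = full0.copy()
            x[free] = xr
            x[~free] = 0.0
            return x

        nll = lambda xr: -self.loglike(expand(xr))
        res = minimize(nll, full0[free], method=method, jac="3-point",
                       options={"maxiter": maxiter, "gtol": gtol})
        xhat = expand(res.x)
        converged = bool(res.success)
        if not converged and res.jac is not None:
            # quasi-Newton often stops on "precision loss" from FD gradient
            # noise; accept the point if the score has effectively vanished
            gmax = float(np.max(np.abs(res.jac)))
            if gmax < 1e-3 * max(1.0, abs(res.fun)):
                converged = True
        if not converged:
            logger.warning("optimizer did not converge: %s", res.message)

        cov_full = None
        if compute_cov:
            H = _numerical_hessian(nll, res.x)
            try:
                cov_r = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov_r = np.linalg.pinv(H)
                logger.warning("observed information singular; using pseudo-inverse")
            cov_full = np.full((self.nparams, self.nparams), np.nan)
            ix = np.flatnonzero(free)
            cov_full[np.ix_(ix, ix)] = cov_r

        log_q0, beta = _unpack(xhat, self.k)
        im = IntensityModel(
            baseline_log_q=log_q0, beta=beta,
            covariate_names=self.covariate_names,
            cov_params=cov_full, converged=converged,
            loglike=-res.fun,
        )
        return MarkovPanelResults(self, im, res)


def _numerical_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, float)
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


@dataclass
class HazardRatioEstimate:
    transition: str
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    se_log: float


class MarkovPanelResults:
    """Estimates, uncertainties and diagnostics for a fitted panel CTMC."""

    def __init__(self, model: MarkovPanelModel, intensity_model: IntensityModel, optres):
        self.model = model
        self.intensity_model = intensity_model
        self.optres = optres
        self.params = intensity_model.params
        self.cov_params = intensity_model.cov_params
        self.converged = intensity_model.converged
        self.llf = intensity_model.loglike

    @property
    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full(len(self.params), np.nan)
        return np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    def baseline_intensities(self) -> pd.DataFrame:
        se = self.bse[:4]
        logq = self.intensity_model.baseline_log_q
        return pd.DataFrame({
            "transition": TRANSITION_LABELS,
            "q0": np.exp(logq),
            "ci_low": np.exp(logq - 1.96 * se),
            "ci_high": np.exp(logq + 1.96 * se),
            "se_log": se,
        })

    def hazard_ratios(self) -> pd.DataFrame:
        """Exponentiated covariate effects per transition with Wald 95% CIs."""
        rows = []
        for j, cov in enumerate(self.model.covariate_names):
            for i, label in enumerate(TRANSITION_LABELS):
                if not self.model._free_beta[j, i]:
                    continue
                idx = 4 + j * 4 + i
                b = self.params[idx]
                se = self.bse[idx]
                rows.append({
                    "transition": label,
                    "covariate": cov,
                    "hr": np.exp(b),
                    "ci_low": np.exp(b - 1.96 * se),
                    "ci_high": np.exp(b + 1.96 * se),
                    "se_log": se,
                })
        return pd.DataFrame(rows, columns=["transition", "covariate", "hr",
                                           "ci_low", "ci_high", "se_log"])

    def hazard_ratio_estimates(self) -> list[HazardRatioEstimate]:
        return [HazardRatioEstimate(r.transition, r.covariate, r.hr, r.ci_low,
                                    r.ci_high, r.se_log)
                for r in self.hazard_ratios().itertuples()]

    def generator_matrix(self, z=None) -> np.ndarray:
        return generator_matrix(self.intensity_model, z)

    def transition_probability(self, t: float, z=None) -> np.ndarray:
        return transition_probability(self.generator_matrix(z), t)

    def summary(self) -> str:
        lines = []
        lines.append("Panel-observed 3-state Markov model (LOW <-> HIGH -> DEATH)")
        lines.append("=" * 64)
        lines.append(f"persons: {self.model.data.n_persons}    records: {self.model.data.n_records}")
        lines.append(f"log-likelihood: {self.llf:.3f}    converged: {self.converged}")
        lines.append("")
        lines.append("Baseline intensities (per year)")
        lines.append(self.baseline_intensities().to_string(index=False, float_format="%.4f"))
        hr = self.hazard_ratios()
        if len(hr):
            lines.append("")
            lines.append("Hazard ratios (exp(beta), Wald 95% CI)")
            lines.append(hr.to_string(index=False, float_format="%.4f"))
        return "\n".join(lines)


def panel_log_likelihood(model: IntensityModel, data: PanelDataset) -> float:
    """Log-likelihood of ``data`` under a given :class:`IntensityModel`."""
    m = MarkovPanelModel(data)
    return m.loglike(model.params)


def fit_ctmc(data: PanelDataset, **fit_kwargs) -> MarkovPanelResults:
    """Convenience wrapper: ``MarkovPanelModel(data).fit(**fit_kwargs)``."""
    return MarkovPanelModel(data).fit(**fit_kwargs)
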