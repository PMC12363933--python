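"""Continuous-time multi-state Markov model for interval-censored panels.

Disease states are observed only at survey waves, so exact transition
times are unknown.  The model is a time-homogeneous continuous-time
Markov chain on the 9-state progression graph: the likelihood of a
participant's observation sequence is the product over consecutive
observation pairs of the matrix-exponential transition probability

    P(dt) = expm(Q * dt),   L = prod_i P(dt_i)[s_i, s_{i+1}],

maximised over the log-intensities of the allowed edges (all other
off-diagonal entries of Q are structurally zero, rows sum to zero).
This is the standard panel-data multi-state formulation: intensities are
instantaneous per-year risks, while the data are wave-to-wave jumps.

Derived quantities: transition-probability matrices over arbitrary
horizons, expected first-passage ("absorption") times to the terminal
triple-comorbidity state via the fundamental-matrix linear system, and a
seeded parametric bootstrap comparing absorption times across starting
states (global Hotelling-type test plus Bonferroni-adjusted pairwise
contrasts).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .conditions import DiseaseProfile
from .panel import ID_COL, TIME_COL, WAVE_COL
from .states import N_STATES, StateSpace, assign_state

logger = logging.getLogger(__name__)

_LOG_RATE_BOUNDS = (-12.0, 3.0)  # rates between ~6e-6 and ~20 per year
_P_FLOOR = 1e-300


class PanelDataError(ValueError):
    """An observed state pair is impossible under the transition graph."""


# ---------------------------------------------------------------------------
# intensity-matrix construction and validation


def build_intensity_matrix(rates: dict, state_space: StateSpace) -> np.ndarray:
    """Assemble Q from an {(i, j): rate} dict on allowed 1-indexed edges."""
    Q = np.zeros((N_STATES, N_STATES))
    for (i, j), r in rates.items():
        if not state_space.adjacency[i - 1, j - 1]:
            raise ValueError(f"edge {i}->{j} is not an allowed transition")
        if r < 0:
            raise ValueError(f"negative intensity on edge {i}->{j}")
        Q[i - 1, j - 1] = r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def validate_intensity_matrix(Q: np.ndarray, state_space: StateSpace | None = None) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError("Q must be 9x9")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise ValueError("off-diagonal intensities must be non-negative")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("rows of Q must sum to zero")
    if state_space is not None and (off[~state_space.adjacency] != 0).any():
        raise ValueError("positive intensity on a disallowed edge")


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows are probability distributions."""
    if t < 0:
        raise ValueError("horizon t must be non-negative")
    return linalg.expm(np.asarray(Q, dtype=float) * t)


def expected_absorption_time(Q: np.ndarray, from_state: int | None = None, target: int = N_STATES):
    """Expected years to reach the absorbing ``target`` state.

    Solves (-Q_TT) tau = 1 on the transient block.  States from which the
    target is unreachable under the positive entries of Q get +inf.
    Returns the 9-vector (target entry 0), or a scalar if ``from_state``
    is given (1-indexed).
    """
    Q = np.asarray(Q, dtype=float)
    tgt = target - 1
    reach = np.linalg.matrix_power(
        (Q > 0).astype(np.int64) + np.eye(N_STATES, dtype=np.int64), N_STATES
    ) > 0
    can = reach[:, tgt]
    tau = np.full(N_STATES, np.inf)
    tau[tgt] = 0.0
    idx = [i for i in range(N_STATES) if i != tgt and can[i]]
    if idx:
        sub = -Q[np.ix_(idx, idx)]
        tau[idx] = np.linalg.solve(sub, np.ones(len(idx)))
    if from_state is not None:
        return float(tau[from_state - 1])
    return tau


# ---------------------------------------------------------------------------
# panel → state sequences → interval counts


def panel_to_sequences(panel: pd.DataFrame, trio=("CVD", "MTD", "SMD")):
    """Per-participant (times, states) arrays from a long-format panel."""
    from .conditions import DISEASE_COLUMNS

    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort")
    seqs = []
    flag_cols = list(DISEASE_COLUMNS)
    for pid, g in panel.groupby(ID_COL, sort=False):
        states = np.array(
            [
                assign_state(DiseaseProfile(**{c: int(r[c]) for c in flag_cols}), trio)
                for _, r in g.iterrows()
            ],
            dtype=np.int64,
        )
        seqs.append((pid, g[TIME_COL].to_numpy(dtype=float), states))
    return seqs


def panel_to_sequences_fast(panel: pd.DataFrame, trio=("CVD", "MTD", "SMD")):
    """Vectorised variant of :func:`panel_to_sequences` for large panels."""
    from .conditions import DISEASE_GROUPS

    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort")
    trio = tuple(str(t).upper() for t in trio)
    t1, t2, t3 = (panel[t.lower()].to_numpy(dtype=np.int64) for t in trio)
    nontrio_cols = [g.lower() for g in DISEASE_GROUPS if g not in trio]
    other = panel[nontrio_cols].to_numpy(dtype=np.int64).max(axis=1)
    code = t1 * 4 + t2 * 2 + t3  # trio subset as 3-bit code
    lut = np.array([1, 5, 4, 8, 3, 7, 6, 9], dtype=np.int64)
    states = lut[code]
    states[(code == 0) & (other == 1)] = 2
    ids = panel[ID_COL].to_numpy()
    times = panel[TIME_COL].to_numpy(dtype=float)
    seqs = []
    boundaries = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1], True])
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seqs.append((ids[a], times[a:b], states[a:b]))
    return seqs


def interval_counts(sequences, state_space: StateSpace, dt_decimals: int = 6):
    """Aggregate consecutive observation pairs into {dt: 9x9 count matrix}.

    Raises :class:`PanelDataError` if an observed pair has no multi-step
    path under the allowed-transition graph (naming the participant and
    observation index).
    """
    reach = state_space.reachability()
    counts: dict[float, np.ndarray] = {}
    for pid, times, states in sequences:
        if len(times) < 2:
            continue
        dts = np.round(np.diff(times), dt_decimals)
        for k, dt in enumerate(dts):
            i, j = states[k] - 1, states[k + 1] - 1
            if not reach[i, j]:
                raise PanelDataError(
                    f"participant {pid!r}, observation {k + 1}: transition "
                    f"state {i + 1} -> {j + 1} is impossible under the "
                    "allowed-transition graph"
                )
            counts.setdefault(float(dt), np.zeros((N_STATES, N_STATES), dtype=np.int64))[i, j] += 1
    return counts


def observation_design(sequences):
    """Observation skeleton for simulating bootstrap panels.

    Returns (padded times (n, max_len) with NaN beyond each participant's
    schedule, per-participant lengths, initial states).
    """
    times_list = [np.asarray(t, dtype=float) for _, t, _ in sequences]
    init = np.array([s[0] for _, _, s in sequences], dtype=np.int64)
    lengths = np.array([len(t) for t in times_list], dtype=np.int64)
    padded = np.full((len(times_list), int(lengths.max())), np.nan)
    for i, t in enumerate(times_list):
        padded[i, : len(t)] = t
    return padded, lengths, init


# ---------------------------------------------------------------------------
# likelihood and fitting


@dataclass
class MarkovFit:
    """Fitted intensities and diagnostics for the panel likelihood."""

    Q: np.ndarray
    state_space: StateSpace
    log_likelihood: float
    converged: bool
    edges: tuple[tuple[int, int], ...]
    se_Q: np.ndarray | None = None
    n_participants: int = 0
    n_observations: int = 0
    transition_counts: np.ndarray | None = None  # summed over intervals
    n_starts: int = 1
    message: str = ""
    design: tuple | None = field(default=None, repr=False)

    def rates(self) -> pd.DataFrame:
        rows = []
        for i, j in self.edges:
            rows.append({
                "from_state": i, "to_state": j,
                "rate_per_year": self.Q[i - 1, j - 1],
                "se": np.nan if self.se_Q is None else self.se_Q[i - 1, j - 1],
                "n_interval_transitions": (
                    np.nan if self.transition_counts is None
                    else int(self.transition_counts[i - 1, j - 1])
                ),
            })
        return pd.DataFrame(rows)


def _nll_factory(counts: dict, edges_idx: np.ndarray):
    """Negative log-likelihood over log-intensities of allowed edges.

    ``counts`` maps dt → 9x9 observed-pair counts; entries are
    pre-flattened so each evaluation is one expm per distinct dt.
    """
    terms = []
    for dt, N in counts.items():
        ii, jj = np.nonzero(N)
        terms.append((dt, ii, jj, N[ii, jj].astype(float)))

    def nll(theta: np.ndarray) -> float:
        Q = np.zeros((N_STATES, N_STATES))
        Q[edges_idx[:, 0], edges_idx[:, 1]] = np.exp(theta)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        total = 0.0
        for dt, ii, jj, n in terms:
            P = linalg.expm(Q * dt)
            p = np.clip(P[ii, jj], _P_FLOOR, None)
            total -= float(n @ np.log(p))
        return total

    return nll


def _crude_init(counts: dict, edges: list[tuple[int, int]]) -> np.ndarray:
    """Events / approximate person-time in the origin state, floored."""
    Nsum = sum(counts.values())
    time_in = np.zeros(N_STATES)
    for dt, N in counts.items():
        time_in += N.sum(axis=1) * dt
    q0 = np.empty(len(edges))
    for k, (i, j) in enumerate(edges):
        q0[k] = Nsum[i - 1, j - 1] / max(time_in[i - 1], 1e-9)
    return np.log(np.clip(q0, 1e-3, 5.0))


def fit_intensities(
    sequences,
    state_space: StateSpace,
    init: np.ndarray | dict | None = None,
    n_starts: int = 3,
    seed: int = 0,
    compute_se: bool = True,
    gtol: float = 1e-7,
    warm: bool = False,
) -> MarkovFit:
    """Maximum-likelihood transition intensities from panel sequences.

    ``sequences`` is an iterable of (participant_id, times, states).
    Optimisation is quasi-Newton (L-BFGS-B) on unconstrained
    log-intensities with ``n_starts`` seeded starts (crude occurrence /
    exposure rates plus perturbations) to guard against local optima.
    ``init`` may be a full Q matrix or an {(i, j): rate} dict; with
    ``warm=True`` only that single start is used (bootstrap refits).
    Standard errors come from the observed information on the log scale,
    delta-method transformed to the rate scale.
    """
    sequences = list(sequences)
    counts = interval_counts(sequences, state_space)
    if not counts:
        raise ValueError("no observation intervals: every participant has < 2 records")
    Q_hat, ll_hat, converged, msg, se_Q, n_starts_used = _fit_counts(
        counts, state_space, init=init, n_starts=n_starts, seed=seed,
        compute_se=compute_se, gtol=gtol, warm=warm,
    )
    return MarkovFit(
        Q=Q_hat,
        state_space=state_space,
        log_likelihood=ll_hat,
        converged=converged,
        edges=tuple(state_space.edges),
        se_Q=se_Q,
        n_participants=len(sequences),
        n_observations=int(sum(len(t) for _, t, _ in sequences)),
        transition_counts=sum(counts.values()),
        n_starts=n_starts_used,
        message=msg,
        design=observation_design(sequences),
    )


def _fit_counts(
    counts: dict,
    state_space: StateSpace,
    init=None,
    n_starts: int = 3,
    seed: int = 0,
    compute_se: bool = False,
    gtol: float = 1e-7,
    warm: bool = False,
):
    """Optimiser core over aggregated interval counts."""
    edges = list(state_space.edges)
    edges_idx = np.array([(i - 1, j - 1) for i, j in edges])
    nll = _nll_factory(counts, edges_idx)

    if isinstance(init, dict):
        init = build_intensity_matrix(init, state_space)
    if init is not None:
        theta_init = np.log(
            np.clip(np.asarray(init)[edges_idx[:, 0], edges_idx[:, 1]], 1e-8, None)
        )
    else:
        theta_init = _crude_init(counts, edges)

    rng = np.random.default_rng(seed)
    starts = [theta_init]
    if not warm:
        for _ in range(max(0, n_starts - 1)):
            starts.append(theta_init + rng.normal(0.0, 0.7, size=len(edges)))

    best = None
    for theta0 in starts:
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B",
            bounds=[_LOG_RATE_BOUNDS] * len(edges),
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    theta_hat = best.x
    Q_hat = np.zeros((N_STATES, N_STATES))
    Q_hat[edges_idx[:, 0], edges_idx[:, 1]] = np.exp(theta_hat)
    np.fill_diagonal(Q_hat, -Q_hat.sum(axis=1))

    ll_hat = -best.fun
    converged = bool(best.success) and ll_hat >= -nll(theta_init) - 1e-6

    se_Q = _observed_info_se(nll, theta_hat, edges_idx) if compute_se else None

    msg = best.message if isinstance(best.message, str) else str(best.message)
    if np.isclose(theta_hat, _LOG_RATE_BOUNDS[0], atol=1e-6).any():
        msg += " [some intensities at lower bound: boundary solution]"
    return Q_hat, ll_hat, converged, msg, se_Q, len(starts)


def _observed_info_se(nll, theta_hat: np.ndarray, edges_idx: np.ndarray) -> np.ndarray:
    """Delta-method SEs for the rates from a finite-difference Hessian of
    the negative log-likelihood in log-rate coordinates."""
    k = len(theta_hat)
    h = 1e-4
    H = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            ea = np.eye(k)[a] * h
            eb = np.eye(k)[b] * h
            H[a, b] = H[b, a] = (
                nll(theta_hat + ea + eb) - nll(theta_hat + ea - eb)
                - nll(theta_hat - ea + eb) + nll(theta_hat - ea - eb)
            ) / (4 * h * h)
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        var = np.clip(np.diag(cov), 0.0, None)
    se_log = np.sqrt(var)
    se_Q = np.zeros((N_STATES, N_STATES))
    se_Q[edges_idx[:, 0], edges_idx[:, 1]] = np.exp(theta_hat) * se_log
    return se_Q


def fit_discrete(sequences, state_space: StateSpace) -> pd.DataFrame:
    """Cross-check mode: per-interval multinomial transition frequencies.

    Pools all observation pairs regardless of interval length and
    row-normalises the counts — a discrete-time per-wave estimator, not
    an intensity model.  Useful only as a sanity check on roughly
    regular panels.
    """
    counts = interval_counts(sequences, state_space)
    N = sum(counts.values()).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = N / N.sum(axis=1, keepdims=True)
    for i in range(N_STATES):
        if N[i].sum() == 0:
            P[i] = 0.0
            P[i, i] = 1.0
    return pd.DataFrame(P, index=range(1, 10), columns=range(1, 10))


# ---------------------------------------------------------------------------
# simulation of observed panels under a fitted Q (parametric bootstrap)


def _simulate_state_matrix(Q: np.ndarray, design, rng: np.random.Generator) -> np.ndarray:
    """Vectorised wave-by-wave simulation on the design's schedule.

    Next states are drawn from the exact interval transition matrices
    expm(Q dt) — the distribution of an interval-censored continuous-time
    trajectory.  Returns an (n, max_len) state matrix with 0 beyond each
    participant's last observation.
    """
    padded, lengths, init = design
    n, max_len = padded.shape
    dts = np.round(np.diff(padded, axis=1), 6)
    states = np.zeros((n, max_len), dtype=np.int64)
    states[:, 0] = init
    cur = init.copy()
    P_cache: dict[float, np.ndarray] = {}
    for step in range(1, max_len):
        col = dts[:, step - 1]
        active = np.flatnonzero(lengths > step)
        if len(active) == 0:
            break
        u = rng.random(n)  # draw for all rows to keep streams schedule-independent
        for dt in np.unique(col[active]):
            if dt not in P_cache:
                P = np.clip(linalg.expm(Q * float(dt)), 0.0, None)
                P /= P.sum(axis=1, keepdims=True)
                P_cache[float(dt)] = np.cumsum(P, axis=1)
            idx = active[col[active] == dt]
            cum = P_cache[float(dt)][cur[idx] - 1]
            nxt = (cum < u[idx][:, None]).sum(axis=1) + 1
            np.clip(nxt, 1, N_STATES, out=nxt)
            cur[idx] = nxt
            states[idx, step] = nxt
    return states


def simulate_observations(Q: np.ndarray, design, rng: np.random.Generator):
    """Simulate observed state sequences under Q on a fixed schedule.

    Returns a sequence list [(participant index, times, states)] suitable
    for :func:`fit_intensities`.
    """
    padded, lengths, init = design
    states = _simulate_state_matrix(Q, design, rng)
    return [
        (p, padded[p, : lengths[p]], states[p, : lengths[p]])
        for p in range(len(lengths))
    ]


def _counts_from_state_matrix(states: np.ndarray, design) -> dict[float, np.ndarray]:
    """Aggregate a simulated state matrix into {dt: 9x9 counts}."""
    padded, lengths, _ = design
    dts = np.round(np.diff(padded, axis=1), 6)
    steps = np.arange(1, padded.shape[1])[None, :]
    valid = steps < lengths[:, None]
    frm = states[:, :-1]
    to = states[:, 1:]
    counts: dict[float, np.ndarray] = {}
    finite = valid & np.isfinite(dts)
    for dt in np.unique(dts[finite]):
        m = finite & (dts == dt)
        flat = (frm[m] - 1) * N_STATES + (to[m] - 1)
        counts[float(dt)] = np.bincount(flat, minlength=N_STATES * N_STATES).reshape(
            N_STATES, N_STATES
        )
    return counts


# ---------------------------------------------------------------------------
# absorption-time comparison by parametric bootstrap


@dataclass
class AbsorptionTimeTable:
    """Expected years to the absorbing state with bootstrap uncertainty."""

    times: pd.DataFrame      # state, label, expected_years, ci_low, ci_high
    pairwise: pd.DataFrame   # state_a, state_b, diff_years, se, t, p, p_bonferroni
    global_statistic: float
    global_df: tuple[int, int]
    global_p: float
    n_boot: int
    n_failed: int
    method: str = (
        "parametric bootstrap (simulate panels under fitted Q on the observed "
        "design, refit, recompute absorption times); global Hotelling-type F "
        "on successive contrasts; pairwise t with Bonferroni adjustment"
    )


def compare_absorption_times(
    fit: MarkovFit,
    start_states=(3, 4, 5),
    n_boot: int = 200,
    seed: int = 0,
    max_fail_frac: float = 0.2,
) -> AbsorptionTimeTable:
    """Do expected times to triple comorbidity differ by starting state?

    Parametric bootstrap: ``n_boot`` panels are simulated under the
    fitted Q on the original observation design, each refit (warm-started
    at Q-hat), and the absorption-time vector recomputed.  The bootstrap
    spread estimates the sampling covariance of the fitted times; a
    Hotelling-corrected Wald statistic on the successive contrasts gives
    the global test and pairwise contrasts use bootstrap SEs with
    t-reference (df = B - 1) and Bonferroni adjustment.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not fit.converged:
        raise ValueError("cannot bootstrap from a non-converged fit")
    if fit.design is None:
        raise ValueError("fit carries no observation design")
    if n_boot < 50:
        warnings.warn("n_boot < 50 gives unstable bootstrap covariance", stacklevel=2)

    start_states = tuple(int(s) for s in start_states)
    k = len(start_states)
    rng = np.random.default_rng(seed)
    point = expected_absorption_time(fit.Q)[[s - 1 for s in start_states]]

    boots = np.empty((n_boot, k))
    n_failed = 0
    kept = 0
    for b in range(n_boot):
        sim_states = _simulate_state_matrix(fit.Q, fit.design, rng)
        counts_b = _counts_from_state_matrix(sim_states, fit.design)
        try:
            Q_b, _, ok, _, _, _ = _fit_counts(
                counts_b, fit.state_space, init=fit.Q, warm=True, compute_se=False
            )
        except (PanelDataError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not ok:
            n_failed += 1
            continue
        tau = expected_absorption_time(Q_b)[[s - 1 for s in start_states]]
        if not np.isfinite(tau).all():
            n_failed += 1
            continue
        boots[kept] = tau
        kept += 1
    if n_failed > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed; "
            "increase sample size or inspect the fit"
        )
    boots = boots[:kept]
    B = kept

    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    labels = [fit.state_space.labels[s - 1] for s in start_states]
    times = pd.DataFrame({
        "state": start_states, "label": labels,
        "expected_years": point, "ci_low": lo, "ci_high": hi,
    })

    # pairwise bootstrap-t contrasts
    pairs = [(a, b) for ia, a in enumerate(start_states) for b in start_states[ia + 1:]]
    rows = []
    for a, b in pairs:
        ia, ib = start_states.index(a), start_states.index(b)
        d = point[ia] - point[ib]
        se = boots[:, ia] - boots[:, ib]
        se = float(np.std(se, ddof=1))
        tstat = d / se if se > 0 else np.inf * np.sign(d)
        p = 2 * stats.t.sf(abs(tstat), df=B - 1)
        rows.append({
            "state_a": a, "state_b": b, "diff_years": d, "se": se,
            "t": tstat, "p": p, "p_bonferroni": min(1.0, p * len(pairs)),
        })
    pairwise = pd.DataFrame(rows)

    # global Hotelling-type test on successive contrasts
    C = np.zeros((k - 1, k))
    for r in range(k - 1):
        C[r, r], C[r, r + 1] = 1.0, -1.0
    d = C @ point
    S = np.cov((boots @ C.T).T, ddof=1)
    S = np.atleast_2d(S)
    try:
        T2 = float(d @ np.linalg.solve(S, d))
    except np.linalg.LinAlgError:
        T2 = float(d @ np.linalg.pinv(S) @ d)
    p_dim = k - 1
    F = T2 * (B - p_dim) / (p_dim * (B - 1))
    p_global = float(stats.f.sf(F, p_dim, B - p_dim))

    return AbsorptionTimeTable(
        times=times, pairwise=pairwise,
        global_statistic=F, global_df=(p_dim, B - p_dim), global_p=p_global,
        n_boot=n_boot, n_failed=n_failed,
    )
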