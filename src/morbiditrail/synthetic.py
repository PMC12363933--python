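"""Synthetic ELSA-like cohort with known ground truth.

The real study population (English Longitudinal Study of Ageing) is
access-restricted, so every downstream stage is exercised on synthetic
data whose generating process is fully known:

* a cross-sectional "transaction" sample over the 7 disease systems with
  a planted high-lift trio {CVD, MTD, SMD}, for the association-rule
  stage;
* a longitudinal panel simulated as a continuous-time Markov chain on
  the 9-state progression graph under a known intensity matrix, observed
  only at biennial waves (interval censoring), for the multi-state
  stage;
* burden outcomes drawn from onset-conditional distributions that plant
  skeletal-muscular onset as the most adverse profile, for the burden
  stage.

Defaults describe a realistic obese cohort: 11 biennial waves (~20
years), entry ages centred in the 60s, ~40% of healthy participants
acquiring a first chronic disease within 5 years, and the metabolic
pathway progressing fastest to triple comorbidity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .conditions import DISEASE_COLUMNS, DISEASE_GROUPS
from .states import N_STATES, build_state_space, state_trio_flags
from .markov import build_intensity_matrix, validate_intensity_matrix

#: ground-truth yearly transition intensities on the progression graph;
#: healthy exit rate ≈ 0.105/yr (≈ 40% acquire a disease within 5 years)
#: and the metabolic (state 4) pathway is the fastest route to state 9
DEFAULT_TRUE_RATES: dict[tuple[int, int], float] = {
    (1, 2): 0.035, (1, 3): 0.030, (1, 4): 0.018, (1, 5): 0.022,
    (2, 3): 0.060, (2, 4): 0.040, (2, 5): 0.050,
    (3, 6): 0.070, (3, 7): 0.035,
    (4, 6): 0.100, (4, 8): 0.070,
    (5, 7): 0.040, (5, 8): 0.060,
    (6, 9): 0.090, (7, 9): 0.055, (8, 9): 0.075,
}

#: initial-state mix: mostly healthy or early states, some prevalent cases
DEFAULT_INITIAL_DISTRIBUTION = (0.40, 0.15, 0.12, 0.08, 0.10, 0.05, 0.04, 0.04, 0.02)

#: marginal disease prevalences for the cross-sectional transactions
DEFAULT_PREVALENCES: dict[str, float] = {
    "CVD": 0.32, "MTD": 0.14, "RPD": 0.14, "SMD": 0.22,
    "NRD": 0.12, "MD": 0.05, "CC": 0.05,
}

#: multiplicative co-occurrence boost for planted itemsets (lift scale)
DEFAULT_PLANTED_LIFT: dict[frozenset, float] = {
    frozenset({"CVD", "MTD", "SMD"}): 12.0,
}

#: onset-conditional burden probabilities; SMD onset planted as the most
#: adverse on depression, sleep and work limitation, MTD worst self-rated
#: health — mirroring the qualitative burden ordering being studied
DEFAULT_BURDEN_CONDITIONALS: dict[str, dict[str, float]] = {
    "CVD": {"depressed": 0.035, "work_limited": 0.55, "sleep_adverse": 0.60, "srh_adverse": 0.32},
    "MTD": {"depressed": 0.045, "work_limited": 0.72, "sleep_adverse": 0.65, "srh_adverse": 0.45},
    "SMD": {"depressed": 0.063, "work_limited": 0.74, "sleep_adverse": 0.77, "srh_adverse": 0.38},
    "baseline": {"depressed": 0.030, "work_limited": 0.40, "sleep_adverse": 0.50, "srh_adverse": 0.25},
}

ORDINAL_LEVELS = ("excellent", "very good", "good", "fair", "poor")


def _ordinal_distribution(adverse_mass: float) -> np.ndarray:
    """Five-level distribution with the given {fair, poor} mass."""
    a = float(adverse_mass)
    rest = 1.0 - a
    return np.array([0.2 * rest, 0.3 * rest, 0.5 * rest, 0.6 * a, 0.4 * a])


@dataclass
class SyntheticConfig:
    """Stated world for the generator; all knobs in one place."""

    seed: int = 0
    n_participants: int = 2_000
    n_cross_section: int = 20_000
    wave_interval: float = 2.0
    n_waves: int = 11
    entry_age_mean: float = 62.0
    entry_age_sd: float = 10.0
    sex_ratio_female: float = 0.55
    frac_white: float = 0.95
    bmi_mean: float = 32.5
    bmi_sd: float = 2.5
    trio: tuple[str, str, str] = ("CVD", "MTD", "SMD")
    true_rates: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_RATES))
    initial_state_distribution: tuple = DEFAULT_INITIAL_DISTRIBUTION
    dropout: float = 0.0
    cross_section_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    planted_lift: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_LIFT))
    burden_conditionals: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_BURDEN_CONDITIONALS.items()
    })

    def __post_init__(self) -> None:
        p0 = np.asarray(self.initial_state_distribution, dtype=float)
        if p0.shape != (N_STATES,) or abs(p0.sum() - 1.0) > 1e-9 or (p0 < 0).any():
            raise ValueError("initial_state_distribution must be a 9-probability vector")
        validate_intensity_matrix(self.true_Q, self.state_space)

    @property
    def state_space(self):
        return build_state_space(self.trio)

    @property
    def true_Q(self) -> np.ndarray:
        return build_intensity_matrix(self.true_rates, self.state_space)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


def trajectory_oracle(Q: np.ndarray, p0, t: float) -> np.ndarray:
    """Exact state-occupancy distribution at time t: p0 · expm(Q t)."""
    p0 = np.asarray(p0, dtype=float)
    return p0 @ linalg.expm(np.asarray(Q, dtype=float) * t)


# ---------------------------------------------------------------------------
# cross-sectional transactions with planted co-occurrence


def _forcing_probability(marginals: np.ndarray, boost: float) -> float:
    """Mixture weight that makes the planted itemset's joint probability
    equal boost × ∏ marginals while preserving each marginal.

    With probability π all items in the set are forced on; otherwise they
    are drawn independently with deflated probabilities
    q_i = (p_i − π)/(1 − π).  π solves
    π + (1 − π) ∏ q_i = boost ∏ p_i on [0, min p_i).
    """
    from scipy.optimize import brentq

    target = boost * np.prod(marginals)
    if boost < 1.0:
        raise ValueError("planted boost must be >= 1")
    if target >= marginals.min():
        raise ValueError(
            f"infeasible planted boost: implied joint probability {target:.4f} "
            f"exceeds smallest marginal {marginals.min():.4f}"
        )
    if boost == 1.0:
        return 0.0

    def f(pi: float) -> float:
        q = (marginals - pi) / (1.0 - pi)
        return pi + (1.0 - pi) * np.prod(q) - target

    return float(brentq(f, 0.0, marginals.min() - 1e-12, xtol=1e-14))


def generate_cross_section(config: SyntheticConfig) -> pd.DataFrame:
    """Transactions over the 7 disease systems with demographics.

    Items are drawn independently at the configured marginal prevalences
    except within planted itemsets, whose joint co-occurrence is boosted
    to the configured lift by a forced-co-occurrence mixture.  Planted
    itemsets must be disjoint.  Columns: participant_id, age, age_band,
    sex, and one boolean column per disease group.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cross_section
    prev = {g.upper(): float(p) for g, p in config.cross_section_prevalences.items()}
    if set(prev) != set(DISEASE_GROUPS):
        raise ValueError("cross_section_prevalences must cover all 7 groups")

    planted = {frozenset(str(i).upper() for i in s): float(b)
               for s, b in config.planted_lift.items() if float(b) != 1.0}
    seen: set[str] = set()
    for s in planted:
        if s & seen:
            raise ValueError("planted itemsets must be disjoint")
        seen |= s

    X = np.zeros((n, len(DISEASE_GROUPS)), dtype=bool)
    col = {g: k for k, g in enumerate(DISEASE_GROUPS)}
    free = set(DISEASE_GROUPS)
    for itemset, boost in planted.items():
        items = sorted(itemset)
        p = np.array([prev[i] for i in items])
        pi = _forcing_probability(p, boost)
        q = (p - pi) / (1.0 - pi)
        forced = rng.random(n) < pi
        base = rng.random((n, len(items))) < q[None, :]
        for k, it in enumerate(items):
            X[:, col[it]] = forced | (~forced & base[:, k])
        free -= itemset
    for g in sorted(free):
        X[:, col[g]] = rng.random(n) < prev[g]

    age = np.clip(rng.normal(config.entry_age_mean, config.entry_age_sd, n), 19, 94)
    sex = np.where(rng.random(n) < config.sex_ratio_female, "female", "male")
    from .arm import age_band_label

    df = pd.DataFrame(X, columns=list(DISEASE_GROUPS))
    df.insert(0, "participant_id", [f"X{k:06d}" for k in range(n)])
    df["age"] = np.round(age, 1)
    df["age_band"] = [age_band_label(a) for a in df["age"]]
    df["sex"] = sex
    return df


# ---------------------------------------------------------------------------
# longitudinal panel from the ground-truth intensity matrix


def _gillespie_trajectory(Q: np.ndarray, s0: int, horizon: float, rng) -> tuple[list, list]:
    """Jump times and states of one continuous-time trajectory on [0, horizon]."""
    times = [0.0]
    states = [s0]
    t, s = 0.0, s0
    while True:
        rates = Q[s - 1].copy()
        rates[s - 1] = 0.0
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        s = int(rng.choice(N_STATES, p=rates / total)) + 1
        times.append(t)
        states.append(s)
    return times, states


def generate_panel(config: SyntheticConfig, mode: str = "gillespie"):
    """Simulate the longitudinal panel; returns (panel, ground_truth).

    ``mode="gillespie"`` simulates exact continuous-time trajectories by
    competing exponential clocks and observes them only at wave times —
    the interval censoring the estimator must handle.  ``mode="discrete"``
    draws wave-to-wave jumps directly from expm(Q·Δ) (same observed-data
    law; cross-check mode).

    ``ground_truth`` carries the true Q, each participant's initial state
    and true onset disease, and the config.
    """
    if mode not in ("gillespie", "discrete"):
        raise ValueError("mode must be 'gillespie' or 'discrete'")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_participants
    Q = config.true_Q
    trio = tuple(t.upper() for t in config.trio)
    wave_times = np.arange(config.n_waves) * config.wave_interval
    horizon = wave_times[-1]

    p0 = np.asarray(config.initial_state_distribution, dtype=float)
    init_states = rng.choice(N_STATES, size=n, p=p0) + 1

    # observed states per wave
    obs = np.zeros((n, config.n_waves), dtype=np.int64)
    onset: list[str] = []
    if mode == "discrete":
        from .markov import _simulate_state_matrix

        padded = np.tile(wave_times, (n, 1))
        lengths = np.full(n, config.n_waves, dtype=np.int64)
        obs = _simulate_state_matrix(Q, (padded, lengths, init_states.copy()), rng)
        onset = [_onset_from_path(list(obs[i]), trio) for i in range(n)]
    else:
        for i in range(n):
            jt, js = _gillespie_trajectory(Q, int(init_states[i]), horizon, rng)
            idx = np.searchsorted(jt, wave_times, side="right") - 1
            obs[i] = np.asarray(js, dtype=np.int64)[idx]
            onset.append(_onset_from_path(js, trio))

    # demographics
    age0 = np.clip(rng.normal(config.entry_age_mean, config.entry_age_sd, n), 40, 90)
    sex = np.where(rng.random(n) < config.sex_ratio_female, "female", "male")
    race = np.where(rng.random(n) < config.frac_white, "white", "non-white")
    bmi0 = rng.normal(config.bmi_mean, config.bmi_sd, n)
    bmi_walk = np.cumsum(rng.normal(0.0, 0.4, (n, config.n_waves)), axis=1)
    bmi_walk[:, 0] = 0.0
    nontrio_groups = [g for g in DISEASE_GROUPS if g not in trio]
    nontrio_pick = rng.choice(len(nontrio_groups), size=n)

    # optional monotone dropout after the second wave
    last_wave = np.full(n, config.n_waves - 1, dtype=np.int64)
    if config.dropout > 0:
        alive = np.ones(n, dtype=bool)
        for w in range(2, config.n_waves):
            drop = alive & (rng.random(n) < config.dropout)
            last_wave[drop] = np.minimum(last_wave[drop], w - 1)
            alive &= ~drop

    rows = []
    trio_cols = [t.lower() for t in trio]
    for i in range(n):
        pid = f"P{i:06d}"
        ever_nontrio = False
        for w in range(last_wave[i] + 1):
            s = int(obs[i, w])
            flags = dict.fromkeys(DISEASE_COLUMNS, 0)
            for c, f in zip(trio_cols, state_trio_flags(s)):
                flags[c] = f
            if s == 2:
                ever_nontrio = True
            if ever_nontrio:
                flags[nontrio_groups[nontrio_pick[i]].lower()] = 1
            rows.append({
                "participant_id": pid,
                "wave": w,
                "time_years": float(wave_times[w]),
                "age": round(float(age0[i] + wave_times[w]), 1),
                "sex": sex[i],
                "race": race[i],
                "bmi": round(float(bmi0[i] + bmi_walk[i, w]), 2),
                **flags,
            })
    panel = pd.DataFrame(rows)

    ground_truth = {
        "true_Q": Q,
        "true_rates": dict(config.true_rates),
        "initial_states": init_states,
        "onset": pd.DataFrame({
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "onset_type": onset,
        }),
        "config": config,
    }
    return panel, ground_truth


def _onset_from_path(states: list, trio: tuple[str, str, str]) -> str:
    """Ground-truth onset disease from a state path.

    The onset is the single trio disease present at the first state that
    contains any trio component, provided the path started free of trio
    components; paths that begin in a trio-containing state, or jump
    straight to a multi-component state, are 'ambiguous'.
    """
    first_flags = state_trio_flags(int(states[0]))
    if sum(first_flags) > 0:
        if sum(first_flags) == 1:
            return trio[first_flags.index(1)]
        return "ambiguous"
    for s in states[1:]:
        flags = state_trio_flags(int(s))
        k = sum(flags)
        if k == 1:
            return trio[flags.index(1)]
        if k > 1:
            return "ambiguous"
    return "none"


# ---------------------------------------------------------------------------
# onset-conditional burden outcomes


def generate_burden(config: SyntheticConfig, panel: pd.DataFrame, onsets: pd.DataFrame) -> pd.DataFrame:
    """Attach burden measures at each participant's last observed wave.

    Binary burdens are Bernoulli draws and ordinal burdens categorical
    draws from the onset-conditional tables in the config; participants
    with 'none'/'ambiguous' onset use the baseline conditional.
    """
    rng = np.random.default_rng(config.seed + 2)
    cond = {k.upper() if k != "baseline" else k: v for k, v in config.burden_conditionals.items()}
    onset_map = dict(zip(onsets["participant_id"], onsets["onset_type"]))

    panel = panel.sort_values(["participant_id", "wave"], kind="mergesort").copy()
    for c in ("self_rated_health", "work_limited", "sleep_quality", "depressed"):
        panel[c] = np.nan if c in ("work_limited", "depressed") else pd.NA
    last_idx = panel.groupby("participant_id", sort=False).tail(1).index

    for idx in last_idx:
        pid = panel.at[idx, "participant_id"]
        key = onset_map.get(pid, "none")
        c = cond.get(key if key in ("CVD", "MTD", "SMD") else "baseline", cond["baseline"])
        panel.at[idx, "depressed"] = float(rng.random() < c["depressed"])
        panel.at[idx, "work_limited"] = float(rng.random() < c["work_limited"])
        panel.at[idx, "sleep_quality"] = rng.choice(
            ORDINAL_LEVELS, p=_ordinal_distribution(c["sleep_adverse"])
        )
        panel.at[idx, "self_rated_health"] = rng.choice(
            ORDINAL_LEVELS, p=_ordinal_distribution(c["srh_adverse"])
        )
    return panel
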