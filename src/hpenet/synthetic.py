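"""Synthetic study sessions with known ground truth.

Emulates the study's structure end to end — five z-scale HF series of
L = 1440 samples at 1 Hz across three 8-minute phases (HIGH, BASELINE,
MALFUNCTION), generated from known sparse stable VAR processes whose network
density follows a per-phase regime schedule; independent per-HF missing
segments (geometric gap lengths) at the artefact rate reported for the real
recordings (~20%); and per-minute behavioural records whose Performance
Index tracks the current true network density with a configurable coupling.
Everything needed to score recovery of the ground truth is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cte import BinaryAdjacency
from .neurometrics import HF_NAMES, HFSeries
from .var import VARModel, simulate_var

__all__ = [
    "GroundTruthScenario",
    "SessionData",
    "RecoveryScore",
    "random_sparse_var",
    "generate_session",
    "generate_cohort",
    "score_recovery",
]


@dataclass
class GroundTruthScenario:
    """Full specification of one synthetic session.

    ``phase_density_multipliers`` scale the base network density per phase
    (the regime schedule): the default (1.5, 0.5, 1.0) makes HIGH dense,
    BASELINE sparse and MALFUNCTION intermediate, so the behavioural
    coupling has a known sign to recover.  ``behavioural_coupling`` is the
    linear weight of the current true density in the per-minute Performance
    Index; 0 disconnects behaviour from the network (the null).
    """

    n_processes: int = 5
    order: int = 2
    density: float = 0.4
    coupling: float = 0.35
    diag_range: tuple[float, float] = (0.3, 0.6)
    phases: tuple[str, ...] = ("HIGH", "BASELINE", "MALFUNCTION")
    phase_minutes: int = 8
    fs: float = 1.0
    phase_density_multipliers: tuple[float, ...] = (1.5, 0.5, 1.0)
    phase_coupling_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0)
    missing_rate: float = 0.2
    gap_mean: float = 3.0
    behavioural_coupling: float = 0.5
    performance_base: float = 0.3
    performance_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.density <= 1:
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if self.coupling <= 0:
            raise ValueError("coupling must be positive")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing rate must lie in [0, 0.5]")
        if len(self.phase_density_multipliers) != len(self.phases):
            raise ValueError("one density multiplier per phase is required")
        if len(self.phase_coupling_multipliers) != len(self.phases):
            raise ValueError("one coupling multiplier per phase is required")

    @property
    def n_samples(self) -> int:
        return int(len(self.phases) * self.phase_minutes * 60 * self.fs)

    @property
    def n_minutes(self) -> int:
        return len(self.phases) * self.phase_minutes


@dataclass
class SessionData:
    """One generated session plus its truth bundle."""

    hf: HFSeries
    behavioural: pd.DataFrame
    truth: dict = field(default_factory=dict)


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int


def _stabilize(A: np.ndarray, radius: float = 0.95, max_steps: int = 100) -> np.ndarray:
    """Shrink toward stability: scaling lag k by s**k scales every companion
    eigenvalue by exactly s, so one step lands on the target radius."""
    model = VARModel(A=A, Sigma=np.eye(A.shape[1]))
    for _ in range(max_steps):
        rho = model.spectral_radius()
        if rho <= radius:
            return model.A
        s = radius / rho
        scaled = np.array([model.A[k] * s ** (k + 1) for k in range(model.order)])
        model = VARModel(A=scaled, Sigma=model.Sigma)
    raise RuntimeError(f"could not stabilize the model in {max_steps} shrinkage steps")


def random_sparse_var(
    n: int = 5,
    p: int = 2,
    density: float = 0.4,
    coupling: float = 0.35,
    seed: int | np.random.Generator = 0,
    diag_range: tuple[float, float] = (0.3, 0.6),
    support: np.ndarray | None = None,
    diag: np.ndarray | None = None,
) -> VARModel:
    """Random stable sparse VAR with a known directed support.

    Off-diagonal lag-1 coefficients of magnitude ~ ``coupling`` (random
    sign) sit on a random support of the requested density; diagonal lag-1
    AR terms are drawn from ``diag_range``.  The coefficient tensor is
    shrunk geometrically until the companion spectral radius is <= 0.95.
    An explicit boolean ``support`` (N x N, diagonal ignored) overrides the
    random one; ``diag`` pins the self-coupling terms.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    if coupling <= 0:
        raise ValueError("coupling must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    if support is None:
        n_links = int(round(density * len(pairs)))
        chosen = [pairs[k] for k in rng.permutation(len(pairs))[:n_links]]
        support = np.zeros((n, n), dtype=bool)
        for i, j in chosen:
            support[i, j] = True
    else:
        support = np.asarray(support, dtype=bool).copy()
        np.fill_diagonal(support, False)
    A = np.zeros((p, n, n))
    if diag is None:
        diag = rng.uniform(*diag_range, size=n)
    A[0][np.arange(n), np.arange(n)] = diag
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    mags = coupling * rng.uniform(0.9, 1.1, size=(n, n))
    for i, j in pairs:
        if support[i, j]:
            A[0][j, i] = signs[i, j] * mags[i, j]
    A = _stabilize(A)
    model = VARModel(A=A, Sigma=np.eye(n), meta={"generator": "random_sparse_var"})
    model.meta["support"] = support.tolist()
    return model


def _inject_gaps(
    values: np.ndarray, rate: float, gap_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent per-row missing segments with geometric lengths."""
    n, L = values.shape
    mask = np.zeros((n, L), dtype=bool)
    if rate == 0:
        return mask
    target = rate * L
    for r in range(n):
        while mask[r].sum() < target:
            start = int(rng.integers(L))
            length = int(rng.geometric(1.0 / gap_mean))
            mask[r, start : start + length] = True
    return mask


def generate_session(scenario: GroundTruthScenario) -> SessionData:
    """Generate one full synthetic session from a scenario.

    Phase-wise VAR simulation with state carry-over between phases, per-HF
    gap injection, and per-minute behavioural records whose Performance
    Index is base + coupling * (current true density) + Gaussian noise,
    mapped back onto plausible ISA ratings and reaction times (the recorded
    RT reproduces the target index exactly through the index formula).
    Deterministic per seed.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n = sc.n_processes
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    # nested supports: denser phases include the sparser phases' links
    order_perm = rng.permutation(len(pairs))
    diag = rng.uniform(*sc.diag_range, size=n)
    phase_len = int(sc.phase_minutes * 60 * sc.fs)

    models, supports, densities = [], [], []
    for dm, cm in zip(sc.phase_density_multipliers, sc.phase_coupling_multipliers):
        dens = float(np.clip(sc.density * dm, 1e-9, 1.0))
        n_links = max(1, int(round(dens * len(pairs))))
        support = np.zeros((n, n), dtype=bool)
        for k in order_perm[:n_links]:
            support[pairs[k]] = True
        model = random_sparse_var(
            n=n, p=sc.order, density=dens, coupling=sc.coupling * cm,
            seed=np.random.default_rng(sc.seed + 1), support=support, diag=diag,
        )
        models.append(model)
        supports.append(support)
        densities.append(support.sum() / len(pairs))

    # simulate phase-wise, carrying the last p samples across the boundary
    chunks = []
    carry = None
    for ph, model in enumerate(models):
        sub_seed = int(rng.integers(2**31 - 1))
        if carry is None:
            sim = simulate_var(model, phase_len, seed=sub_seed, burn_in=500)
            chunks.append(sim.values)
        else:
            sim = simulate_var(model, phase_len + sc.order, seed=sub_seed, burn_in=0)
            # splice: overwrite the seed samples with the carried state
            x = sim.values.copy()
            x[:, : sc.order] = carry
            # re-run the recursion deterministically from the carried state
            w = _innovations_of(sim.values, model)
            for t in range(sc.order, phase_len + sc.order):
                acc = w[:, t]
                for k in range(sc.order):
                    acc = acc + model.A[k] @ x[:, t - 1 - k]
                x[:, t] = acc
            chunks.append(x[:, sc.order :])
        carry = chunks[-1][:, -sc.order :]
    values = np.hstack(chunks)
    assert values.shape == (n, sc.n_samples)

    mask = _inject_gaps(values, sc.missing_rate, sc.gap_mean, rng)
    gapped = values.copy()
    gapped[mask] = np.nan
    names = HF_NAMES if n == len(HF_NAMES) else tuple(f"x{i+1}" for i in range(n))
    hf = HFSeries(values=gapped, names=names, mask=mask)

    # behavioural records, one per minute
    minutes = np.arange(sc.n_minutes)
    phase_of_minute = [sc.phases[m // sc.phase_minutes] for m in minutes]
    dens_of_minute = np.array([densities[m // sc.phase_minutes] for m in minutes])
    target_pi = (
        sc.performance_base
        + sc.behavioural_coupling * dens_of_minute
        + rng.normal(0.0, sc.performance_noise, size=sc.n_minutes)
    )
    target_pi = np.clip(target_pi, 0.05, None)
    sme_by_phase = {ph: int(rng.integers(2, 5)) for ph in sc.phases}
    atco = rng.integers(2, 5, size=sc.n_minutes)
    sme = np.array([sme_by_phase[ph] for ph in phase_of_minute])
    rt = (sme / atco) / target_pi
    behavioural = pd.DataFrame(
        {
            "minute": minutes,
            "phase": phase_of_minute,
            "atco_isa": atco,
            "atco_rt_s": rt,
            "sme_isa": sme,
        }
    )
    truth = {
        "scenario": sc,
        "models": models,
        "supports": supports,
        "densities": densities,
        "density_per_minute": dens_of_minute,
        "performance_index": target_pi,
        "seed": sc.seed,
    }
    return SessionData(hf=hf, behavioural=behavioural, truth=truth)


def _innovations_of(x: np.ndarray, model: VARModel) -> np.ndarray:
    """Back out the innovation sequence of a simulated trajectory."""
    p = model.order
    w = x.copy()
    for t in range(p, x.shape[1]):
        pred = np.zeros(x.shape[0])
        for k in range(p):
            pred += model.A[k] @ x[:, t - 1 - k]
        w[:, t] = x[:, t] - pred
    return w


def generate_cohort(
    scenario: GroundTruthScenario, n_subjects: int = 17, seed: int = 0
) -> list[SessionData]:
    """A cohort of independent sessions sharing one scenario; per-subject
    seeds are derived from ``seed`` so the cohort is reproducible."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_subjects):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        sub = GroundTruthScenario(**{**scenario.__dict__, "seed": sub_seed})
        out.append(generate_session(sub))
    return out


def score_recovery(truth_support, fitted) -> RecoveryScore:
    """Precision / recall / F1 of a fitted directed support vs the truth,
    over the off-diagonal cells."""
    truth = np.asarray(truth_support, dtype=bool)
    pred = fitted.Mbin if isinstance(fitted, BinaryAdjacency) else np.asarray(fitted, bool)
    if truth.shape != pred.shape:
        raise ValueError("truth and fitted adjacency shapes differ")
    off = ~np.eye(truth.shape[0], dtype=bool)
    t, f = truth[off], pred[off]
    tp = int((t & f).sum())
    fp = int((~t & f).sum())
    fn = int((t & ~f).sum())
    tn = int((~t & ~f).sum())
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return RecoveryScore(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn, tn=tn)
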