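"""The Human Performance Envelope: HF* coefficients, pentagon, area, windows.

Each human factor's contribution at time t is the composite coefficient

    HF*(i, t) = PR(i, t) * D(t) / H(i, t)            (clipped to [0, 1])

combining node centrality (PageRank), global network cohesion (density) and
organizational uncertainty (entropy).  The five coefficients are placed at
fixed angular positions 72 degrees apart and the enclosed polygon area —
computed with the shoelace formula — is the scalar HPE at time t.  Time
resolution comes from re-estimating the sparse VAR in sliding windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cte import BinaryAdjacency, binarize, cte_matrix
from .graph import ENTROPY_FLOOR, graph_indexes
from .neurometrics import HFSeries
from .var import fit_var_lasso, select_lambda, select_order

__all__ = [
    "HPEFrame",
    "HPESeries",
    "VERTEX_ANGLES_DEG",
    "MAX_AREA",
    "hf_star",
    "polygon_vertices",
    "polygon_area",
    "sliding_window_hpe",
    "best_worst_contrast",
    "plot_hpe_frame",
]

#: Fixed vertex angles (degrees): vertex k at 90 + 72 k, in HF listing order.
VERTEX_ANGLES_DEG = 90.0 + 72.0 * np.arange(5)

#: Area of the all-ones pentagon (unit circumradius): (5/2) sin 72 deg.
MAX_AREA = 2.5 * np.sin(np.deg2rad(72.0))


def hf_star(pr_i: float, density: float, entropy_i: float) -> tuple[float, bool]:
    """One HF* coefficient: (PR * D) / H, clipped into [0, 1].

    Returns (value, clipped) so callers can count clip events.  Entropy must
    already be clamped at the floor; anything below it is a caller bug.
    """
    if entropy_i < ENTROPY_FLOOR:
        raise ValueError(
            f"entropy {entropy_i} below the floor {ENTROPY_FLOOR}; "
            "apply the clamp before building HF*"
        )
    raw = (pr_i * density) / entropy_i
    clipped = raw > 1.0
    return (1.0 if clipped else max(raw, 0.0)), bool(clipped)


def polygon_vertices(radii) -> np.ndarray:
    """Planar coordinates of the five HF vertices at the fixed angles."""
    r = np.asarray(radii, dtype=float)
    if r.shape != (5,):
        raise ValueError("exactly five radii are required")
    theta = np.deg2rad(VERTEX_ANGLES_DEG)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def polygon_area(radii) -> float:
    """Shoelace (Gauss) area of the HF pentagon with the given radii."""
    v = polygon_vertices(radii)
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


@dataclass
class HPEFrame:
    """One time-resolved HPE sample (a fitted window)."""

    t: float  # window centre, seconds
    t_start: int
    t_stop: int
    hf_star: np.ndarray = None
    vertices: np.ndarray = None
    area: float = np.nan
    adjacency: BinaryAdjacency = None
    n_links: int = 0
    n_clipped: int = 0
    ok: bool = True
    failure: str = ""


@dataclass
class HPESeries:
    """HPE frames over a session plus the provenance needed to re-run it."""

    frames: list[HPEFrame]
    window: int
    step: int
    provenance: dict = field(default_factory=dict)

    @property
    def areas(self) -> np.ndarray:
        return np.array([f.area for f in self.frames])

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    def per_minute(self, n_minutes: int) -> np.ndarray:
        """Per-minute HPE vector of length ``n_minutes``.

        Frames are averaged within the minute containing their centre;
        minutes without a frame are filled by linear interpolation over
        frame centres (constant extrapolation at the session edges).
        """
        ok = np.array([f.ok for f in self.frames])
        if not ok.any():
            raise ValueError("no successful frames to aggregate")
        centers = self.centers[ok]
        areas = self.areas[ok]
        out = np.empty(n_minutes)
        for m in range(n_minutes):
            in_minute = (centers >= 60 * m) & (centers < 60 * (m + 1))
            if in_minute.any():
                out[m] = areas[in_minute].mean()
            else:
                out[m] = np.interp(60 * m + 30.0, centers, areas)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.frames:
            row = {
                "t_center": f.t,
                "t_start": f.t_start,
                "t_stop": f.t_stop,
                "area": f.area,
                "n_links": f.n_links,
                "n_clipped": f.n_clipped,
                "ok": f.ok,
            }
            if f.hf_star is not None:
                for k, v in enumerate(f.hf_star):
                    row[f"hf_star_{k + 1}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _frame_from_adjacency(
    adj: BinaryAdjacency, t_start: int, t_stop: int, damping: float, entropy_mode: str
) -> HPEFrame:
    gi = graph_indexes(adj, damping=damping, entropy_mode=entropy_mode)
    radii = np.empty(adj.n_nodes)
    n_clip = 0
    for i in range(adj.n_nodes):
        radii[i], clipped = hf_star(gi.pr[i], gi.density, gi.entropy[i])
        n_clip += clipped
    return HPEFrame(
        t=(t_start + t_stop) / 2.0,
        t_start=t_start,
        t_stop=t_stop,
        hf_star=radii,
        vertices=polygon_vertices(radii),
        area=polygon_area(radii),
        adjacency=adj,
        n_links=adj.n_edges,
        n_clipped=n_clip,
    )


def sliding_window_hpe(
    series: HFSeries,
    window: int = 120,
    step: int = 60,
    p: int | None = None,
    p_max: int = 20,
    lambda_per_row=None,
    lambda_policy: str = "session",
    grid=None,
    n_folds: int = 10,
    binarize_rule: str = "exact-zero",
    damping: float = 0.85,
    entropy_mode: str = "node",
    seed: int = 0,
) -> HPESeries:
    """Time-resolved HPE by per-window re-estimation of the sparse VAR.

    The model order is selected once on the whole session (or passed in);
    the per-row penalty is, by default, also selected once on the whole
    session and reused inside every window (``lambda_policy="session"``),
    which stabilizes the small-sample window fits; ``"window"`` re-selects
    it per window.  Each window is fitted with LASSO, converted to cTE,
    binarized, and summarized into an HF* pentagon and its area.  A window
    whose fit degenerates is flagged and skipped, not fatal.
    """
    series.require_gap_free("sliding-window HPE")
    L = series.n_samples
    if step < 1:
        raise ValueError("step must be >= 1")
    if p is None:
        sel = select_order(series, p_max=p_max)
        p = sel.p
    if window <= 10 * p:
        raise ValueError(f"window ({window}) must exceed 10*p ({10 * p})")
    if lambda_per_row is None and lambda_policy == "session":
        lam_sel = select_lambda(series, p, grid=grid, k=n_folds, seed=seed)
        lambda_per_row = lam_sel.lambda_per_row
    frames: list[HPEFrame] = []
    starts = range(0, L - window + 1, step)
    for t0 in starts:
        sub = HFSeries(
            values=series.values[:, t0 : t0 + window],
            names=series.names,
            standardized=series.standardized,
        )
        try:
            if lambda_policy == "window" and lambda_per_row is None:
                lam = select_lambda(sub, p, grid=grid, k=min(n_folds, 5), seed=seed)
                lam_row = lam.lambda_per_row
            else:
                lam_row = lambda_per_row
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model, _ = fit_var_lasso(sub, p, lam_row)
            result = cte_matrix(model)
            adj = binarize(result, rule=binarize_rule)
            frames.append(
                _frame_from_adjacency(adj, t0, t0 + window, damping, entropy_mode)
            )
        except (ValueError, np.linalg.LinAlgError, RuntimeError, AssertionError) as exc:
            frames.append(
                HPEFrame(
                    t=(2 * t0 + window) / 2.0,
                    t_start=t0,
                    t_stop=t0 + window,
                    ok=False,
                    failure=str(exc),
                )
            )
    provenance = {
        "window": window,
        "step": step,
        "p": int(p),
        "lambda_policy": lambda_policy,
        "lambda_per_row": None
        if lambda_per_row is None
        else np.asarray(lambda_per_row).tolist(),
        "binarize_rule": binarize_rule,
        "damping": damping,
        "entropy_mode": entropy_mode,
        "seed": seed,
        "n_failed_frames": sum(not f.ok for f in frames),
    }
    return HPESeries(frames=frames, window=window, step=step, provenance=provenance)


@dataclass
class BestWorstFrames:
    """Per-subject HPE (and link counts) at the best/worst performance minute."""

    best: np.ndarray
    worst: np.ndarray
    best_minutes: np.ndarray
    worst_minutes: np.ndarray
    best_links: np.ndarray = None
    worst_links: np.ndarray = None


def best_worst_contrast(
    hpe_per_minute: list[np.ndarray],
    perf_per_minute: list[np.ndarray],
    links_per_minute: list[np.ndarray] | None = None,
) -> BestWorstFrames:
    """Pick each subject's HPE at the argmax/argmin performance minute.

    Ties in the performance extremum resolve to the earliest minute.  The
    paired vectors feed the best-vs-worst t-test downstream.
    """
    if len(hpe_per_minute) != len(perf_per_minute):
        raise ValueError("one performance vector per HPE vector is required")
    best, worst, bm, wm, bl, wl = [], [], [], [], [], []
    for s, (hpe, perf) in enumerate(zip(hpe_per_minute, perf_per_minute)):
        hpe = np.asarray(hpe, dtype=float)
        perf = np.asarray(perf, dtype=float)
        if hpe.shape != perf.shape:
            raise ValueError(f"subject {s}: HPE and performance lengths differ")
        if len(perf) < 2:
            raise ValueError(f"subject {s}: need at least two minutes for a contrast")
        b, w = int(np.argmax(perf)), int(np.argmin(perf))
        best.append(hpe[b])
        worst.append(hpe[w])
        bm.append(b)
        wm.append(w)
        if links_per_minute is not None:
            bl.append(links_per_minute[s][b])
            wl.append(links_per_minute[s][w])
    return BestWorstFrames(
        best=np.array(best),
        worst=np.array(worst),
        best_minutes=np.array(bm),
        worst_minutes=np.array(wm),
        best_links=np.array(bl) if links_per_minute is not None else None,
        worst_links=np.array(wl) if links_per_minute is not None else None,
    )


def plot_hpe_frame(radii, path=None, ax=None, labels=None, **kwargs):
    """Radar-style pentagon of one HF* vector; writes SVG/PNG when ``path``
    is given.  Returns the matplotlib axes."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .neurometrics import HF_NAMES

    labels = HF_NAMES if labels is None else labels
    v = polygon_vertices(radii)
    closed = np.vstack([v, v[0]])
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(closed[:, 0], closed[:, 1], **({"color": "tab:green"} | kwargs))
    ax.fill(closed[:, 0], closed[:, 1], alpha=0.25, color=kwargs.get("color", "tab:green"))
    unit = polygon_vertices(np.ones(5))
    ax.plot(np.append(unit[:, 0], unit[0, 0]), np.append(unit[:, 1], unit[0, 1]),
            ls=":", lw=0.8, color="grey")
    for (x, y), lb in zip(unit, labels):
        ax.annotate(lb, (1.12 * x, 1.12 * y), ha="center", va="center", fontsize=8)
    ax.set_aspect("equal")
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.axis("off")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
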