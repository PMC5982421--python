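"""Drilling-state classification from fitted frequency-distribution coefficients.

A 4-3-1 feed-forward network maps the min--max-normalized coefficient
vector ``(a, b, c, d)`` of one frame to a score in ``[0, 1]``: 0 means
dense bone (cortical or cancellous), 1 means the transition region.  The
hidden layer uses the log-sigmoid transfer, the output layer is linear,
and training minimizes mean squared error with Levenberg--Marquardt using
the analytic Jacobian of all 19 free parameters.

Scores are hardened with a dead zone: values at or below 0.1 become 0,
values at or above 0.9 become 1, and anything in between is reported as
UNDECIDED rather than silently rounded.

Independently of the network, :func:`detect_boundaries` finds layer
changes directly in the coefficient time series: at a true boundary the
coefficients jump at the same time, so a boundary is declared only where
at least ``quorum`` of the four robust jump scores exceed a threshold
simultaneously.  The default quorum of 3 reflects that the amplitude
coefficient ``a`` is weakly identified on near-flat transition curves and
its jump can fall below any usable threshold, while ``b``, ``c`` and
``d`` step sharply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UNDECIDED",
    "NormalizationBounds",
    "Mlp431",
    "TrainConfig",
    "TrainHistory",
    "LayerTimeline",
    "BoundaryParams",
    "minmax_fit",
    "minmax_apply",
    "init_mlp",
    "forward",
    "train_lm",
    "harden_output",
    "harden_scores",
    "recognition_rate",
    "detect_boundaries",
]

#: Sentinel label for scores inside the (0.1, 0.9) dead zone.
UNDECIDED = -1

N_INPUT, N_HIDDEN = 4, 3
N_PARAMS = N_HIDDEN * N_INPUT + N_HIDDEN + N_HIDDEN + 1  # = 19


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-coefficient min/max estimated on the training corpus."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        if mins.shape != maxs.shape:
            raise ValueError("mins and maxs must have the same shape")
        if np.any(maxs <= mins):
            raise ValueError("every coefficient needs max > min")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationBounds":
        return cls(mins=np.array(d["mins"]), maxs=np.array(d["maxs"]))


def minmax_fit(features: np.ndarray) -> NormalizationBounds:
    """Estimate min--max normalization bounds, column by column."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 rows")
    mins, maxs = x.min(axis=0), x.max(axis=0)
    if np.any(maxs <= mins):
        bad = np.flatnonzero(maxs <= mins)
        raise ValueError(f"constant feature column(s) {bad.tolist()}: cannot scale")
    return NormalizationBounds(mins=mins, maxs=maxs)


def minmax_apply(features: np.ndarray, bounds: NormalizationBounds) -> np.ndarray:
    """``x' = (x - min) / (max - min)``, clamped to [0, 1] out of range.

    Clamping handles test-time values outside the training range.
    """
    x = np.asarray(features, dtype=float)
    scaled = (x - bounds.mins) / (bounds.maxs - bounds.mins)
    return np.clip(scaled, 0.0, 1.0)


@dataclass
class Mlp431:
    """Weights of the 4-3-1 network (19 free parameters)."""

    w_hidden: np.ndarray  # (3, 4)
    b_hidden: np.ndarray  # (3,)
    w_out: np.ndarray     # (3,)
    b_out: float

    def __post_init__(self) -> None:
        self.w_hidden = np.asarray(self.w_hidden, dtype=float).reshape(N_HIDDEN, N_INPUT)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float).reshape(N_HIDDEN)
        self.w_out = np.asarray(self.w_out, dtype=float).reshape(N_HIDDEN)
        self.b_out = float(self.b_out)

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.w_hidden.ravel(), self.b_hidden, self.w_out, [self.b_out]]
        )

    @classmethod
    def unpack(cls, theta: np.ndarray) -> "Mlp431":
        theta = np.asarray(theta, dtype=float)
        if theta.size != N_PARAMS:
            raise ValueError(f"expected {N_PARAMS} parameters, got {theta.size}")
        nw = N_HIDDEN * N_INPUT
        return cls(
            w_hidden=theta[:nw].reshape(N_HIDDEN, N_INPUT),
            b_hidden=theta[nw:nw + N_HIDDEN],
            w_out=theta[nw + N_HIDDEN:nw + 2 * N_HIDDEN],
            b_out=theta[-1],
        )

    def to_dict(self) -> dict:
        return {
            "architecture": "mlp-4-3-1-logsig-purelin",
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mlp431":
        if d.get("architecture") != "mlp-4-3-1-logsig-purelin":
            raise ValueError(f"unknown architecture tag {d.get('architecture')!r}")
        return cls(
            w_hidden=np.array(d["w_hidden"]),
            b_hidden=np.array(d["b_hidden"]),
            w_out=np.array(d["w_out"]),
            b_out=d["b_out"],
        )


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg--Marquardt training settings.

    ``learning_rate`` is the initial damping of the LM step (the role the
    value 0.001 plays in classic `trainlm`-style trainers), adapted by
    factors of 10 as steps succeed or fail.
    """

    max_epochs: int = 2000
    goal: float = 1e-6
    learning_rate: float = 0.001
    seed: int = 0
    damping_max: float = 1e10

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or not self.goal > 0:
            raise ValueError("max_epochs >= 1 and goal > 0 required")


@dataclass
class TrainHistory:
    mse: list[float] = field(default_factory=list)
    epochs: int = 0
    converged: bool = False
    stop_reason: str = ""

    def summary(self) -> dict:
        return {
            "epochs": self.epochs,
            "final_mse": self.mse[-1] if self.mse else None,
            "converged": self.converged,
            "stop_reason": self.stop_reason,
        }


def _logsig(z: np.ndarray) -> np.ndarray:
    # numerically safe log-sigmoid
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_mlp(seed: int) -> Mlp431:
    """Seeded uniform [-0.5, 0.5] initialization of all 19 parameters."""
    rng = np.random.default_rng(seed)
    return Mlp431.unpack(rng.uniform(-0.5, 0.5, N_PARAMS))


def forward(model: Mlp431, inputs: np.ndarray) -> np.ndarray:
    """Raw network score(s) for one 4-vector or an (n, 4) batch."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    if x.shape[1] != N_INPUT:
        raise ValueError(f"expected {N_INPUT} inputs per sample, got {x.shape[1]}")
    hidden = _logsig(x @ model.w_hidden.T + model.b_hidden)
    scores = hidden @ model.w_out + model.b_out
    return scores if np.asarray(inputs).ndim == 2 else float(scores[0])


def _forward_jacobian(theta: np.ndarray, x: np.ndarray):
    """Scores and d(score)/d(theta) for a batch; J has shape (n, 19)."""
    model = Mlp431.unpack(theta)
    hidden = _logsig(x @ model.w_hidden.T + model.b_hidden)   # (n, 3)
    scores = hidden @ model.w_out + model.b_out
    dh = hidden * (1.0 - hidden)                              # logsig'
    g = dh * model.w_out                                      # (n, 3)
    j_w = g[:, :, None] * x[:, None, :]                       # (n, 3, 4)
    jac = np.concatenate(
        [j_w.reshape(x.shape[0], -1), g, hidden, np.ones((x.shape[0], 1))],
        axis=1,
    )
    return scores, jac


def train_lm(
    inputs: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[Mlp431, TrainHistory]:
    """Train the 4-3-1 network by damped Gauss--Newton (Levenberg--Marquardt).

    Each epoch solves ``(J'J + mu*I) step = -J'r`` and accepts the step only
    if it lowers the mean squared error, dividing the damping ``mu`` by 10 on
    success and multiplying by 10 on failure.  Stops at the error goal, the
    epoch limit, or when the damping overflows ``damping_max`` (recorded in
    the history, not raised).  Fully deterministic for a fixed seed.
    """
    config = config or TrainConfig()
    x = np.asarray(inputs, dtype=float)
    t = np.asarray(targets, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_INPUT:
        raise ValueError(f"inputs must be (n, {N_INPUT})")
    if t.shape != (x.shape[0],):
        raise ValueError("targets must be a vector matching inputs")
    if x.shape[0] < 20:
        raise ValueError("need at least 20 training samples")
    if np.any((t < 0) | (t > 1)):
        raise ValueError("targets must lie in [0, 1]")

    n = x.shape[0]
    theta = init_mlp(config.seed).pack()
    scores, jac = _forward_jacobian(theta, x)
    resid = scores - t
    mse = float(resid @ resid) / n
    mu = config.learning_rate
    history = TrainHistory(mse=[mse])
    eye = np.eye(N_PARAMS)

    for epoch in range(1, config.max_epochs + 1):
        if mse <= config.goal:
            history.converged = True
            history.stop_reason = "goal reached"
            break
        grad = jac.T @ resid
        jtj = jac.T @ jac
        stepped = False
        while mu <= config.damping_max:
            try:
                step = np.linalg.solve(jtj + mu * eye, -grad)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta + step
            cand_scores, cand_jac = _forward_jacobian(cand, x)
            cand_resid = cand_scores - t
            cand_mse = float(cand_resid @ cand_resid) / n
            if cand_mse < mse:
                theta, scores, jac, resid, mse = (
                    cand, cand_scores, cand_jac, cand_resid, cand_mse
                )
                mu = max(mu / 10.0, 1e-20)
                stepped = True
                break
            mu *= 10.0
        history.mse.append(mse)
        history.epochs = epoch
        if not stepped:
            history.stop_reason = "damping overflow (local minimum)"
            break
    else:
        history.stop_reason = "max epochs"
    if mse <= config.goal:
        history.converged = True
        if not history.stop_reason:
            history.stop_reason = "goal reached"
    return Mlp431.unpack(theta), history


def harden_output(score: float) -> int:
    """Map a raw score to {0, 1, UNDECIDED} with the 0.1/0.9 dead zone.

    Scores outside [0, 1] are clamped first, so anything at or below 0.1
    hardens to 0 and anything at or above 0.9 hardens to 1.
    """
    s = min(max(float(score), 0.0), 1.0)
    if s <= 0.1:
        return 0
    if s >= 0.9:
        return 1
    return UNDECIDED


def harden_scores(scores: np.ndarray) -> np.ndarray:
    s = np.clip(np.asarray(scores, dtype=float), 0.0, 1.0)
    out = np.full(s.shape, UNDECIDED, dtype=int)
    out[s <= 0.1] = 0
    out[s >= 0.9] = 1
    return out


@dataclass(frozen=True)
class LayerTimeline:
    """Per-frame state sequence with optional scores and boundary times."""

    times: np.ndarray
    labels: np.ndarray                      # 0, 1 or UNDECIDED
    scores: np.ndarray | None = None
    boundaries: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if times.shape != labels.shape:
            raise ValueError("times and labels must match in length")
        if self.boundaries is not None:
            b = np.asarray(self.boundaries, dtype=float)
            if b.size > 1 and np.any(np.diff(b) <= 0):
                raise ValueError("boundary times must be strictly increasing")
            object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "labels", labels)


def recognition_rate(
    predicted: LayerTimeline, truth: LayerTimeline, policy: str = "strict"
) -> float:
    """Fraction of frames whose hardened label matches the reference.

    ``strict``: UNDECIDED frames count as wrong.
    ``nearest``: UNDECIDED frames are resolved to whichever of {0, 1} the
    raw score is closer to (requires scores on the predicted timeline).
    """
    if predicted.labels.size != truth.labels.size:
        raise ValueError("predicted and truth timelines differ in length")
    pred = predicted.labels.copy()
    if policy == "nearest":
        if predicted.scores is None:
            raise ValueError("nearest policy needs raw scores")
        undecided = pred == UNDECIDED
        pred[undecided] = (predicted.scores[undecided] >= 0.5).astype(int)
    elif policy != "strict":
        raise ValueError(f"unknown policy {policy!r}")
    return float(np.mean(pred == truth.labels))


@dataclass(frozen=True)
class BoundaryParams:
    """Settings of the synchronized-jump boundary detector.

    ``window`` frames of smoothed coefficients on each side feed the jump
    score; ``threshold`` is in robust z-units of each coefficient's own
    local-level variability; jumps in different coefficients within
    ``tolerance`` frames of each other count as simultaneous; detected
    events must be at least ``refractory_s`` seconds apart.  Within a
    gated region the event is placed at the peak of the summed jump
    scores recomputed with the shorter ``loc_window``, which localizes a
    step more sharply than the wide detection window.  ``quorum`` is the
    number of coefficients (of 4) that must jump together; a step in a
    single coefficient is never a boundary.
    """

    window: int = 25
    threshold: float = 3.0
    tolerance: int = 12
    refractory_s: float = 1.0
    median_smooth: int = 5
    loc_window: int = 8
    quorum: int = 3


def _moving_median(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    from scipy.ndimage import median_filter

    return median_filter(x.astype(float), size=w, mode="nearest")


def _jump_scores(col: np.ndarray, w: int, smooth: int) -> np.ndarray:
    """|median after - median before| / robust scale, at every frame.

    The scale is the MAD of the median-difference series itself, so it
    reflects how much the column's local level wanders within a layer
    (slow drift included) while staying insensitive to the few genuine
    boundary spikes.
    """
    sm = _moving_median(col, smooth)
    n = sm.size
    diffs = np.zeros(n)
    for i in range(w, n - w):
        diffs[i] = np.median(sm[i:i + w]) - np.median(sm[i - w:i])
    valid = diffs[w:n - w]
    scale = 1.4826 * np.median(np.abs(valid - np.median(valid)))
    scale = max(scale, 1e-12)
    return np.abs(diffs) / scale


def detect_boundaries(
    times: np.ndarray,
    coeffs: np.ndarray,
    params: BoundaryParams | None = None,
) -> np.ndarray:
    """Find instants where all four coefficients jump simultaneously.

    Parameters
    ----------
    times : (n,) frame times in seconds
    coeffs : (n, 4) fitted coefficient series, columns (a, b, c, d)

    Returns
    -------
    Strictly increasing boundary times (possibly empty).
    """
    params = params or BoundaryParams()
    times = np.asarray(times, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 2 or coeffs.shape[1] != 4:
        raise ValueError("coeffs must be an (n, 4) matrix")
    n = coeffs.shape[0]
    if n < 2 * params.window:
        raise ValueError(
            f"series too short: {n} frames < 2*window={2 * params.window}"
        )

    scores = np.column_stack(
        [_jump_scores(coeffs[:, j], params.window, params.median_smooth)
         for j in range(4)]
    )
    if not 2 <= params.quorum <= 4:
        raise ValueError("quorum must be between 2 and 4")
    # a coefficient "fires" at frame i if it exceeds the threshold within
    # +/- tolerance frames; a boundary needs `quorum` firing at once
    exceeds = scores > params.threshold
    tol = params.tolerance
    fired = np.zeros_like(exceeds)
    for j in range(4):
        idx = np.flatnonzero(exceeds[:, j])
        for i in idx:
            fired[max(0, i - tol):i + tol + 1, j] = True
    joint = fired.sum(axis=1) >= params.quorum
    if not joint.any():
        return np.array([])

    # gate decides existence; the sharply localizing summed score decides
    # the position inside each gated region.  Two boundaries flanking a
    # short layer can share one gated region, so events are found by peak
    # picking with a refractory minimum separation rather than by taking
    # one maximum per region.
    from scipy.signal import find_peaks

    loc_scores = np.column_stack(
        [_jump_scores(coeffs[:, j], params.loc_window, params.median_smooth)
         for j in range(4)]
    )
    strength = np.where(joint, loc_scores.sum(axis=1), 0.0)
    dt = float(np.median(np.diff(times))) if n > 1 else 1.0
    distance = max(int(round(params.refractory_s / dt)), 1)
    peaks, _ = find_peaks(strength, distance=distance)
    peaks = peaks[joint[peaks]]
    return times[peaks]
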