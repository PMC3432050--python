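"""Synthetic ROI time series with known directed connectivity.

Four regions of interest (default: left inferior frontal gyrus, insula,
caudate nucleus, precuneus) evolve as a structural vector autoregression

    eta_t = A eta_t + Phi eta_{t-1} + c_t + zeta_t,

i.e. eta_t = (I - A)^-1 (Phi eta_{t-1} + c_t + zeta_t), with contemporaneous
coefficients A (zero diagonal), lag-1 coefficients Phi, white Gaussian
residuals zeta and a box-car task mean shift c_t.  The scan schedule mirrors
a block design: 8 task blocks of 26 s (a 2 s instruction scan plus six
trials) interleaved with 16 s fixation periods, sampled at TR = 2 s, which
gives 176 scans.  Stationarity requires the companion matrix
(I - A)^-1 Phi to have spectral radius below 1.

A behavioral-table generator plants a known accuracy-working-memory
correlation through a Gaussian copula, with age independent, for testing
the partial-correlation statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

__all__ = [
    "DEFAULT_ROI_NAMES",
    "ConnectivityGroundTruth",
    "DesignSchedule",
    "ROITimeSeries",
    "StationarityError",
    "make_schedule",
    "simulate_subject",
    "simulate_group",
    "simulate_behavior",
    "stationary_covariance",
    "default_truth",
]

DEFAULT_ROI_NAMES = ("IFG", "INS", "CN", "PCu")

TASK_BLOCK_SECONDS = 26
INSTRUCTION_SECONDS = 2
REST_SECONDS = 16
WARMUP_SAMPLES = 20
JITTER_MAX_RETRIES = 100


class StationarityError(ValueError):
    """The implied lag-1 system is not stationary."""


@dataclass(frozen=True)
class ConnectivityGroundTruth:
    """Ground-truth network: contemporaneous A, lagged Phi, residual SDs.

    Convention: ``A[i, j]`` is the directed effect of ROI j on ROI i
    (row = target), and likewise for ``Phi`` one scan later.
    """

    A: np.ndarray
    Phi: np.ndarray
    noise_sd: np.ndarray
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES

    def __post_init__(self) -> None:
        p = len(self.roi_names)
        A = np.asarray(self.A, dtype=float)
        Phi = np.asarray(self.Phi, dtype=float)
        sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (p,)).copy()
        if A.shape != (p, p) or Phi.shape != (p, p):
            raise ValueError(f"A and Phi must be {p}x{p}")
        if np.any(np.diag(A) != 0):
            raise ValueError("A must have a zero diagonal")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Phi", Phi)
        object.__setattr__(self, "noise_sd", sd)

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    def companion(self) -> np.ndarray:
        """(I - A)^-1 Phi, the reduced-form lag-1 transition matrix."""
        I = np.eye(self.n_roi)
        if abs(np.linalg.det(I - self.A)) < 1e-12:
            raise StationarityError("(I - A) is singular")
        return np.linalg.solve(I - self.A, self.Phi)

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def check_stationary(self) -> None:
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise StationarityError(
                f"spectral radius of (I-A)^-1 Phi is {rho:.3f} >= 1"
            )


@dataclass(frozen=True)
class DesignSchedule:
    """Per-scan condition labels for the block design."""

    tr_seconds: float
    n_blocks: int
    block_seconds: int
    instruction_seconds: int
    rest_seconds: int
    condition_labels: tuple[str, ...]  # 'task' | 'fixation' per scan
    instruction_scans: tuple[bool, ...]

    @property
    def n_scans(self) -> int:
        return len(self.condition_labels)

    def mask(self, condition: str) -> np.ndarray:
        return np.array([c == condition for c in self.condition_labels])

    def segments(self) -> list[tuple[str, int, int]]:
        """Contiguous (condition, start, stop) runs of scans."""
        out = []
        start = 0
        labels = self.condition_labels
        for t in range(1, len(labels) + 1):
            if t == len(labels) or labels[t] != labels[start]:
                out.append((labels[start], start, t))
                start = t
        return out


def make_schedule(n_blocks: int = 8, tr_seconds: float = 2.0) -> DesignSchedule:
    """Alternating fixation/task schedule, fixation first and last.

    8 blocks at TR = 2 s give 8 x 13 task scans + 9 x 8 fixation scans
    = 176 scans.  The first scan of each task block is the instruction
    period.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    for name, seconds in (
        ("task block", TASK_BLOCK_SECONDS),
        ("rest period", REST_SECONDS),
        ("instruction period", INSTRUCTION_SECONDS),
    ):
        if (seconds / tr_seconds) % 1 != 0:
            raise ValueError(
                f"TR {tr_seconds} s does not divide the {name} ({seconds} s)"
            )
    task_scans = int(TASK_BLOCK_SECONDS / tr_seconds)
    rest_scans = int(REST_SECONDS / tr_seconds)
    instr_scans = int(INSTRUCTION_SECONDS / tr_seconds)
    labels: list[str] = ["fixation"] * rest_scans
    instruction: list[bool] = [False] * rest_scans
    for _ in range(n_blocks):
        labels += ["task"] * task_scans
        instruction += [True] * instr_scans + [False] * (task_scans - instr_scans)
        labels += ["fixation"] * rest_scans
        instruction += [False] * rest_scans
    return DesignSchedule(
        tr_seconds=tr_seconds,
        n_blocks=n_blocks,
        block_seconds=TASK_BLOCK_SECONDS,
        instruction_seconds=INSTRUCTION_SECONDS,
        rest_seconds=REST_SECONDS,
        condition_labels=tuple(labels),
        instruction_scans=tuple(instruction),
    )


@dataclass(frozen=True)
class ROITimeSeries:
    """Per-subject T x p matrix of ROI signals plus the scan schedule."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    schedule: DesignSchedule
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"data must be T x {len(self.roi_names)}, got {data.shape}"
            )
        if data.shape[0] < 20:
            raise ValueError("need at least 20 scans")
        if np.isnan(data).any():
            raise ValueError("data contains missing values")
        if data.shape[0] != self.schedule.n_scans:
            raise ValueError(
                f"data has {data.shape[0]} scans but schedule has "
                f"{self.schedule.n_scans}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_scans(self) -> int:
        return int(self.data.shape[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.roi_names))
        df.insert(0, "condition", list(self.schedule.condition_labels))
        df.insert(0, "scan_index", np.arange(self.n_scans))
        df.insert(0, "subject_id", self.subject_id)
        return df


def stationary_covariance(truth: ConnectivityGroundTruth) -> np.ndarray:
    """Closed-form stationary covariance of eta via the discrete Lyapunov
    equation  V = B V B' + Q  with B = (I-A)^-1 Phi and
    Q = (I-A)^-1 D (I-A)^-T, D = diag(noise_sd^2)."""
    truth.check_stationary()
    B = truth.companion()
    I = np.eye(truth.n_roi)
    M = np.linalg.inv(I - truth.A)
    Q = M @ np.diag(truth.noise_sd**2) @ M.T
    return solve_discrete_lyapunov(B, Q)


def simulate_subject(
    truth: ConnectivityGroundTruth,
    schedule: DesignSchedule,
    task_gain: float = 0.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sub-01",
    baseline_level: float = 100.0,
) -> ROITimeSeries:
    """Simulate one subject's ROI series under the block design.

    The task effect is a box-car mean shift of ``task_gain`` (same for all
    ROIs) injected through the structural equation during task scans.
    ``baseline_level`` is a constant raw-signal offset added to every scan
    (scanner-units resting level) so that percent signal change against
    the fixation baseline is well defined; it does not affect covariances.
    Twenty warm-up samples (fixation condition) are discarded.
    """
    truth.check_stationary()
    rng = np.random.default_rng(seed)
    p = truth.n_roi
    T = schedule.n_scans
    I = np.eye(p)
    Minv = np.linalg.inv(I - truth.A)
    task = schedule.mask("task")
    eta = np.zeros(p)
    out = np.empty((T, p))
    noise = rng.normal(size=(WARMUP_SAMPLES + T, p)) * truth.noise_sd
    for t in range(WARMUP_SAMPLES + T):
        c = 0.0
        if t >= WARMUP_SAMPLES and task[t - WARMUP_SAMPLES]:
            c = task_gain
        eta = Minv @ (truth.Phi @ eta + c + noise[t])
        if t >= WARMUP_SAMPLES:
            out[t - WARMUP_SAMPLES] = eta
    return ROITimeSeries(
        subject_id=subject_id,
        data=out + baseline_level,
        tr_seconds=schedule.tr_seconds,
        schedule=schedule,
        roi_names=truth.roi_names,
    )


def _jitter_truth(
    truth: ConnectivityGroundTruth,
    sd: float,
    rng: np.random.Generator,
) -> ConnectivityGroundTruth:
    """Gaussian jitter on the nonzero coefficients, truncated to stationarity."""
    if sd == 0:
        return truth
    for _ in range(JITTER_MAX_RETRIES):
        A = truth.A + rng.normal(scale=sd, size=truth.A.shape) * (truth.A != 0)
        Phi = truth.Phi + rng.normal(scale=sd, size=truth.Phi.shape) * (
            truth.Phi != 0
        )
        candidate = replace(truth, A=A, Phi=Phi)
        try:
            candidate.check_stationary()
        except StationarityError:
            continue
        return candidate
    raise StationarityError(
        f"jitter sd={sd} broke stationarity {JITTER_MAX_RETRIES} times"
    )


def simulate_group(
    truth: ConnectivityGroundTruth,
    schedule: DesignSchedule,
    n_subjects: int = 20,
    between_subject_sd: float = 0.0,
    task_gain: float = 0.0,
    seed: int = 0,
    baseline_level: float = 100.0,
) -> list[ROITimeSeries]:
    """Simulate a group; per-subject seeds are spawned deterministically
    from the master seed, and per-subject coefficients get truncated
    Gaussian jitter (sd = ``between_subject_sd``) on the nonzero entries."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subject_truth = _jitter_truth(truth, between_subject_sd, rng)
        out.append(
            simulate_subject(
                subject_truth,
                schedule,
                task_gain=task_gain,
                seed=rng,
                subject_id=f"sub-{i + 1:02d}",
                baseline_level=baseline_level,
            )
        )
    return out


def simulate_behavior(
    n_subjects: int,
    accuracy_mean: float = 0.57,
    accuracy_sd: float = 0.08,
    wm_corr: float = 0.564,
    wm_mean: float = 6.0,
    wm_sd: float = 1.1,
    age_mean: float = 21.0,
    age_sd: float = 2.0,
    group: str = "explicit",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Behavioral table with a planted accuracy-WM correlation.

    Accuracy and working-memory score are drawn from a Gaussian copula
    with correlation ``wm_corr``; age is independent of both, so the
    age-controlled partial correlation equals ``wm_corr`` in population.
    Accuracies are clipped to [0, 1].  Defaults echo the scale of a
    letter-number-sequencing working-memory score and the above-chance
    accuracy range typical of AGL grammaticality judgments.
    """
    if not -1 < wm_corr < 1:
        raise ValueError("|wm_corr| must be < 1")
    if not 0 < accuracy_mean < 1:
        raise ValueError("accuracy_mean must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, wm_corr], [wm_corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_subjects)
    age = age_mean + age_sd * rng.normal(size=n_subjects)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(n_subjects)],
            "group": group,
            "accuracy": np.clip(accuracy_mean + accuracy_sd * z[:, 0], 0.0, 1.0),
            "wm_score": wm_mean + wm_sd * z[:, 1],
            "age": np.abs(age),
        }
    )


def default_truth(roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES) -> ConnectivityGroundTruth:
    """A sparse 6-edge demonstration network over the four default ROIs.

    Contemporaneous chain IFG -> INS -> CN -> PCu (last edge negative) with
    a negative PCu -> IFG feedback, plus two lagged cross-edges
    (IFG -> CN, INS -> PCu) and autoregression 0.3 on every node.
    """
    p = len(roi_names)
    if p != 4:
        raise ValueError("default truth is defined for 4 ROIs")
    A = np.zeros((4, 4))
    A[1, 0] = 0.50   # IFG -> INS
    A[2, 1] = 0.45   # INS -> CN
    A[3, 2] = -0.40  # CN -> PCu
    A[0, 3] = -0.35  # PCu -> IFG
    Phi = np.eye(4) * 0.3
    Phi[2, 0] = 0.40  # IFG(t) -> CN(t+1)
    Phi[3, 1] = 0.40  # INS(t) -> PCu(t+1)
    truth = ConnectivityGroundTruth(
        A=A, Phi=Phi, noise_sd=np.ones(4), roi_names=roi_names
    )
    truth.check_stationary()
    return truth
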