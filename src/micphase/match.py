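"""Phase identification by spectral matching weighted by formation energy.

The pipeline: normalize the experimental diffractogram, fit a continuous
model of intensity versus 2-theta to it (a smoothing spline by default, or a
small seeded feed-forward network), do the same for the simulated pattern of
every candidate polymorph, and score each candidate by

    score = MAE / p,

where MAE is the mean absolute error between the two models on a common
2-theta grid (normalized-intensity units) and p is the candidate's formation
probability, a Boltzmann softmax over per-atom formation energies at an
effective temperature T_eff:

    p_i = exp(-E_i / k T_eff) / sum_j exp(-E_j / k T_eff).

Lower formation energy means a higher prior probability of forming, so at
comparable spectral error the thermodynamically favored polymorph wins.  The
candidate with the lowest score is the identified phase.

T_eff is a weighting knob, not a physical temperature: at the default
10^4 K the ~0.3 eV/atom spread among the plausible CaCO3 polymorphs yields a
strong but non-degenerate prior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .structures import CandidatePhase
from .xrd import CU_KA1, PowderPattern, ProfileConfig, normalize_pattern, simulate_pattern

__all__ = [
    "BOLTZMANN_EV_PER_K",
    "MatchConfig",
    "SpectrumModel",
    "MatchResult",
    "formation_probability",
    "preprocess_experimental",
    "fit_spectrum_model",
    "mae_between",
    "rank_candidates",
    "identify_phase",
]

logger = logging.getLogger(__name__)

BOLTZMANN_EV_PER_K = 8.617333262e-5


@dataclass(frozen=True)
class MatchConfig:
    """Knobs of the matching pipeline; defaults mirror a 20-60 deg Cu Ka scan."""

    t_eff: float = 1e4  # K, Boltzmann weighting temperature
    grid_min: float = 20.0
    grid_max: float = 60.0
    grid_step: float = 0.02
    model_kind: str = "spline"  # or "network"
    seed: int = 42
    # 64 tanh units are the narrowest single layer that resolves the ~30
    # pseudo-Voigt peaks of a carbonate scan; narrower nets blur the spectrum
    # and the probability prior starts to dominate the match
    network_width: int = 64
    network_epochs: int = 2000
    background_degree: int = -1  # -1 disables background removal
    # smoothing-spline penalty on the [0,1]-scaled axis; small enough to keep
    # 0.15-deg-wide peaks at full height while still damping grid-scale noise
    spline_lam: float = 1e-9

    def __post_init__(self) -> None:
        if self.t_eff <= 0:
            raise ValueError("t_eff must be positive")
        if self.model_kind not in ("spline", "network"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.grid_min >= self.grid_max or self.grid_step <= 0:
            raise ValueError("invalid evaluation grid")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)

    @property
    def profile(self) -> ProfileConfig:
        return ProfileConfig(
            grid_step=self.grid_step, scan_min=self.grid_min, scan_max=self.grid_max
        )


@dataclass
class SpectrumModel:
    """A fitted continuous model of normalized intensity versus 2-theta."""

    model_kind: str
    predict: Callable[[np.ndarray], np.ndarray]
    training_loss: float
    seed: int
    x_range: tuple[float, float]

    def __call__(self, two_theta) -> np.ndarray:
        return np.asarray(self.predict(np.asarray(two_theta, dtype=float)))


@dataclass
class MatchResult:
    materials_id: str
    space_group: str
    mae: float
    probability: float
    score: float
    rank: int = 0


def formation_probability(
    candidates: list[CandidatePhase], t_eff: float = MatchConfig.t_eff
) -> dict[str, float]:
    """Boltzmann softmax over per-atom formation energies (eV) at T_eff (K)."""
    if not candidates:
        raise ValueError("candidate list must not be empty")
    if t_eff <= 0:
        raise ValueError("t_eff must be positive")
    energies = np.array([c.formation_energy for c in candidates])
    x = -energies / (BOLTZMANN_EV_PER_K * t_eff)
    x -= np.max(x)
    w = np.exp(x)
    p = w / np.sum(w)
    return {c.materials_id: float(pi) for c, pi in zip(candidates, p)}


def _rolling_min(y: np.ndarray, half_window: int) -> np.ndarray:
    out = np.empty_like(y)
    for i in range(len(y)):
        lo = max(0, i - half_window)
        out[i] = np.min(y[lo : i + half_window + 1])
    return out


def preprocess_experimental(
    pattern: PowderPattern, config: MatchConfig = MatchConfig()
) -> PowderPattern:
    """Resample to the evaluation grid, optionally strip background, normalize.

    Background removal (``background_degree >= 0``) fits a polynomial of that
    degree to the rolling minima of the resampled signal and subtracts it;
    negative residuals are clipped to zero before normalizing to max 100.
    """
    grid = config.grid
    eps = 1e-9
    if pattern.two_theta[0] > grid[0] + eps or pattern.two_theta[-1] < grid[-1] - eps:
        raise ValueError(
            "pattern coverage "
            f"[{pattern.two_theta[0]:.3f}, {pattern.two_theta[-1]:.3f}] does not span "
            f"the evaluation grid [{grid[0]:.3f}, {grid[-1]:.3f}]"
        )
    if np.array_equal(pattern.two_theta, grid):
        y = pattern.intensity.copy()
    else:
        y = np.interp(grid, pattern.two_theta, pattern.intensity)
    if config.background_degree >= 0:
        half_window = max(2, int(round(1.0 / config.grid_step)))  # ~2 deg window
        baseline_pts = _rolling_min(y, half_window)
        coeffs = np.polyfit(grid, baseline_pts, config.background_degree)
        y = np.clip(y - np.polyval(coeffs, grid), 0.0, None)
    return normalize_pattern(
        PowderPattern(wavelength=pattern.wavelength, two_theta=grid, intensity=y)
    )


def fit_spectrum_model(
    pattern: PowderPattern, config: MatchConfig = MatchConfig()
) -> SpectrumModel:
    """Fit the continuous intensity model to a normalized pattern.

    ``spline``: cubic smoothing spline with a fixed small penalty
    (deterministic).  ``network``: a single-hidden-layer tanh regressor
    trained full-batch by L-BFGS from a seed-determined initialization.
    2-theta is scaled to [0, 1] in both cases.
    """
    x = pattern.two_theta
    y = pattern.intensity
    if x.size < 10:
        raise ValueError(f"need at least 10 grid points to fit, got {x.size}")
    lo, hi = float(x[0]), float(x[-1])
    xs = (x - lo) / (hi - lo)

    if config.model_kind == "spline":
        spl = make_smoothing_spline(xs, y, lam=config.spline_lam)

        def predict(tt, _spl=spl, _lo=lo, _hi=hi):
            return np.clip(_spl((np.asarray(tt, dtype=float) - _lo) / (_hi - _lo)), 0.0, None)

    else:
        from sklearn.neural_network import MLPRegressor

        net = MLPRegressor(
            hidden_layer_sizes=(config.network_width,),
            activation="tanh",
            solver="lbfgs",
            max_iter=config.network_epochs,
            random_state=config.seed,
            tol=1e-8,
        )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(xs.reshape(-1, 1), y)

        def predict(tt, _net=net, _lo=lo, _hi=hi):
            xq = (np.asarray(tt, dtype=float).reshape(-1, 1) - _lo) / (_hi - _lo)
            return np.clip(_net.predict(xq), 0.0, None)

    training_loss = float(np.mean(np.abs(predict(x) - y)))
    return SpectrumModel(
        model_kind=config.model_kind,
        predict=predict,
        training_loss=training_loss,
        seed=config.seed,
        x_range=(lo, hi),
    )


def _evaluate(obj, grid: np.ndarray) -> np.ndarray:
    if isinstance(obj, SpectrumModel):
        return obj(grid)
    if isinstance(obj, PowderPattern):
        return np.interp(grid, obj.two_theta, obj.intensity)
    raise TypeError(f"cannot evaluate {type(obj).__name__} on a grid")


def mae_between(a, b, grid) -> float:
    """Mean absolute error between two models/patterns on a 2-theta grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("evaluation grid must not be empty")
    return float(np.mean(np.abs(_evaluate(a, grid) - _evaluate(b, grid))))


def rank_candidates(
    experimental: PowderPattern,
    candidates: list[CandidatePhase],
    config: MatchConfig = MatchConfig(),
    wavelength: float = CU_KA1,
    candidate_patterns: dict[str, PowderPattern] | None = None,
) -> list[MatchResult]:
    """Score every candidate with a structure and sort ascending by score.

    Candidates without an atomic structure cannot be simulated; they are
    skipped with a warning and excluded from the probability normalization.
    ``candidate_patterns`` may supply precomputed simulated patterns (keyed by
    materials id) to avoid re-simulating across repeated calls; simulation is
    deterministic, so this is purely a cache.
    """
    usable = [c for c in candidates if c.structure is not None]
    skipped = [c.materials_id for c in candidates if c.structure is None]
    if skipped:
        logger.warning("skipping candidates without structures: %s", ", ".join(skipped))
    if not usable:
        raise RuntimeError("no candidate has an atomic structure to simulate")

    probs = formation_probability(usable, config.t_eff)
    grid = config.grid
    exp_model = fit_spectrum_model(preprocess_experimental(experimental, config), config)

    results = []
    for cand in usable:
        if candidate_patterns is not None and cand.materials_id in candidate_patterns:
            sim = candidate_patterns[cand.materials_id]
        else:
            sim = simulate_pattern(cand.structure, config.profile, wavelength)
            if candidate_patterns is not None:
                candidate_patterns[cand.materials_id] = sim
        sim_model = fit_spectrum_model(normalize_pattern(sim), config)
        mae = mae_between(exp_model, sim_model, grid)
        p = probs[cand.materials_id]
        results.append(
            (mae / p, cand.formation_energy, MatchResult(
                materials_id=cand.materials_id,
                space_group=cand.space_group,
                mae=mae,
                probability=p,
                score=mae / p,
            ))
        )
    results.sort(key=lambda t: (t[0], t[1]))
    ranked = [r for _, _, r in results]
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


def identify_phase(
    experimental: PowderPattern,
    candidates: list[CandidatePhase],
    config: MatchConfig = MatchConfig(),
    wavelength: float = CU_KA1,
    candidate_patterns: dict[str, PowderPattern] | None = None,
) -> MatchResult:
    """The rank-1 candidate: lowest MAE per formation probability."""
    return rank_candidates(experimental, candidates, config, wavelength, candidate_patterns)[0]
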