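"""Simulated 2AFC staircase experiments in (f_peak, sigma) space.

Each trial shows a reference noise patch and two alternatives; one
alternative shares the reference NPS (different realization), the other comes
from an NPS offset along a direction in (f_peak, sigma) space.  The offset
magnitude follows a transformed up-down staircase: after three consecutive
correct responses it shrinks by 15% of its current value, after any error it
grows by 15%, so the procedure converges on the ~79.4% ("80%") correct point
of the psychometric curve.  A run stops after 12 reversals and is summarized
by the geometric mean of the offsets at the last 8 reversal trials; a full
experiment repeats each direction 6 times, discards the first repetition as
practice, and averages the remaining 5 estimates into the direction's
detectability threshold.

Eight canonical directions are studied: +/- f_peak only, +/- sigma only, and
the four diagonals (both parameters changing, unit vectors).  For diagonal
directions the staircase variable is the scalar magnitude along the
direction vector, so the Delta-f_peak : Delta-sigma ratio stays locked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InfeasibleTargetError
from .nps_models import TwoParamDescriptor
from .nps_synthesis import (
    DEFAULT_PIXEL_SPACING_CM,
    build_nps2d,
    model_nps1d,
    solve_model_params,
    synthesize_noise,
)
from .observer import SpectrumHypothesis, decide_2afc

__all__ = [
    "Direction",
    "canonical_directions",
    "StaircaseConfig",
    "StaircaseState",
    "staircase_update",
    "Trial",
    "make_trial",
    "max_feasible_offset",
    "StaircaseResult",
    "run_staircase",
    "DirectionThreshold",
    "ExperimentResult",
    "run_experiment",
]

_SQ2 = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class Direction:
    """A unit direction in (f_peak, sigma) space."""

    u_fpeak: float
    u_sigma: float
    index: int = 0

    def __post_init__(self):
        norm = math.hypot(self.u_fpeak, self.u_sigma)
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            raise DomainError("direction must be a unit vector")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.u_fpeak, self.u_sigma])


def canonical_directions() -> list[Direction]:
    """The eight studied directions, indexed 1-8.

    1: +f_peak, 2: -f_peak, 3: +sigma, 4: -sigma, 5: both up, 6: both down,
    7: +f_peak/-sigma, 8: -f_peak/+sigma.
    """
    spec = [(1, 1.0, 0.0), (2, -1.0, 0.0), (3, 0.0, 1.0), (4, 0.0, -1.0),
            (5, _SQ2, _SQ2), (6, -_SQ2, -_SQ2), (7, _SQ2, -_SQ2),
            (8, -_SQ2, _SQ2)]
    return [Direction(u_fpeak=uf, u_sigma=us, index=i) for i, uf, us in spec]


@dataclass(frozen=True)
class StaircaseConfig:
    """Rules of the adaptive procedure."""

    step_fraction: float = 0.15
    n_down: int = 3
    n_up: int = 1
    stop_reversals: int = 12
    reversals_used: int = 8
    repetitions: int = 6
    repetitions_used: int = 5
    start_offset: float = 1.0
    max_trials: int = 200
    # "reversal_offsets": geometric mean of the offsets at the reversal
    # trials (default); "trials_between": geometric mean of every trial
    # offset from the first of the used reversals onward.
    reversal_aggregation: str = "reversal_offsets"
    # "complement": down-step multiplies by (1 - step_fraction), the literal
    # "15% of the current value" reading; "reciprocal": divides by
    # (1 + step_fraction), making up/down steps symmetric on the log scale
    # (the convergence point then sits exactly at the 3-down-1-up 79.4%).
    step_down_mode: str = "complement"

    def __post_init__(self):
        if not 0.0 < self.step_fraction < 1.0:
            raise DomainError("step_fraction must be in (0, 1)")
        if self.reversals_used > self.stop_reversals:
            raise DomainError("reversals_used cannot exceed stop_reversals")
        if self.repetitions_used > self.repetitions:
            raise DomainError("repetitions_used cannot exceed repetitions")
        if self.start_offset <= 0:
            raise DomainError("start_offset must be positive")


@dataclass
class TrialRecord:
    offset: float
    correct: bool
    reversal: bool


@dataclass
class StaircaseState:
    """Mutable state of one 3-down-1-up run."""

    config: StaircaseConfig
    offset: float
    max_offset: float = math.inf
    consecutive_correct: int = 0
    last_step: int = 0  # -1 down, +1 up, 0 none yet
    trials: list = field(default_factory=list)
    reversal_offsets: list = field(default_factory=list)
    ceiling_hits: int = 0
    ever_stepped_up: bool = False

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_offsets)

    @property
    def done(self) -> bool:
        return (self.n_reversals >= self.config.stop_reversals
                or len(self.trials) >= self.config.max_trials)


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Record one response and apply the 3-down-1-up rule in place.

    Down-steps multiply the offset by ``1 - step_fraction`` after ``n_down``
    consecutive correct responses; any error multiplies it by
    ``1 + step_fraction`` and resets the counter.  A reversal is logged at the
    trial where the step direction changes, with the offset presented on that
    trial.  Up-steps are capped at ``max_offset`` (infeasible-offset ceiling).
    """
    cfg = state.config
    presented = state.offset
    step = 0
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= cfg.n_down:
            state.consecutive_correct = 0
            if cfg.step_down_mode == "reciprocal":
                state.offset = presented / (1.0 + cfg.step_fraction)
            else:
                state.offset = presented * (1.0 - cfg.step_fraction)
            step = -1
    else:
        state.consecutive_correct = 0
        new = presented * (1.0 + cfg.step_fraction)
        if new > state.max_offset:
            new = state.max_offset
            state.ceiling_hits += 1
        state.offset = new
        state.ever_stepped_up = True
        step = +1
    reversal = step != 0 and state.last_step != 0 and step != state.last_step
    if step != 0:
        state.last_step = step
    if reversal:
        state.reversal_offsets.append(presented)
    state.trials.append(TrialRecord(presented, correct, reversal))
    return state


def _ref_params(ref) -> tuple[float, float]:
    if isinstance(ref, TwoParamDescriptor):
        if ref.sigma is None:
            raise InfeasibleTargetError("reference has no downslope sigma")
        return ref.f_peak, ref.sigma
    fp, sg = ref
    return float(fp), float(sg)


def max_feasible_offset(ref, direction: Direction, *,
                        pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM,
                        margin: float = 1e-3) -> float:
    """Largest offset keeping the offset NPS parameters realizable.

    Both parameters must stay positive and f_peak must stay below the grid
    Nyquist; negative-going components bound the offset (a too-large
    negative-sigma offset would need sigma < 0, which does not exist).
    """
    fp, sg = _ref_params(ref)
    nyq = 1.0 / (2.0 * pixel_spacing_cm)
    bounds = []
    if direction.u_fpeak < 0:
        bounds.append((margin - fp) / direction.u_fpeak)
    elif direction.u_fpeak > 0:
        bounds.append((nyq * 0.95 - fp) / direction.u_fpeak)
    if direction.u_sigma < 0:
        bounds.append((margin - sg) / direction.u_sigma)
    return min(bounds) if bounds else math.inf


@dataclass(frozen=True)
class Trial:
    """One 2AFC presentation: reference patch, two alternatives, ground truth."""

    reference: object
    alternatives: tuple
    correct_index: int
    ref_hypothesis: SpectrumHypothesis
    alt_hypothesis: SpectrumHypothesis
    offset_vector: np.ndarray


def _hypothesis_cache_key(fp: float, sg: float) -> tuple[float, float]:
    return (round(fp, 9), round(sg, 9))


class _NPSCache:
    """Caches solved model curves and 2-D spectra per (f_peak, sigma)."""

    def __init__(self, grid_size: int, pixel_spacing_cm: float):
        self.grid_size = grid_size
        self.pixel_spacing_cm = pixel_spacing_cm
        self._store: dict = {}

    def nps2d(self, fp: float, sg: float):
        key = _hypothesis_cache_key(fp, sg)
        if key not in self._store:
            alpha, beta = solve_model_params(
                fp, sg, pixel_spacing_cm=self.pixel_spacing_cm)
            curve = model_nps1d(alpha, beta,
                                pixel_spacing_cm=self.pixel_spacing_cm)
            self._store[key] = build_nps2d(curve, self.grid_size)
        return self._store[key]


def make_trial(ref, direction: Direction, offset: float, seed, *,
               grid_size: int = 128,
               pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM,
               mu: float = 0.0, sd: float = 25.0,
               cache: _NPSCache | None = None) -> Trial:
    """Build one trial: three synthesized patches plus the ground truth.

    The reference patch and the matching alternative share the reference NPS
    with different noise seeds; the odd alternative uses the NPS at
    ``ref + offset * direction``.  The correct (matching) alternative's index
    is drawn uniformly from the trial seed.
    """
    fp, sg = _ref_params(ref)
    vec = offset * direction.vector
    fp_alt, sg_alt = fp + vec[0], sg + vec[1]
    if fp_alt <= 0 or sg_alt <= 0:
        raise InfeasibleTargetError(
            f"offset {offset:g} along direction {direction.index} yields "
            f"non-positive parameters ({fp_alt:g}, {sg_alt:g})")
    cache = cache or _NPSCache(grid_size, pixel_spacing_cm)
    ref2d = cache.nps2d(fp, sg)
    alt2d = cache.nps2d(fp_alt, sg_alt)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    s_ref, s_match, s_odd, s_pos = ss.spawn(4)
    patch_ref = synthesize_noise(ref2d, mu, sd, s_ref)
    patch_match = synthesize_noise(ref2d, mu, sd, s_match)
    patch_odd = synthesize_noise(alt2d, mu, sd, s_odd)
    correct_index = int(np.random.default_rng(s_pos).integers(2))
    alts = ((patch_match, patch_odd) if correct_index == 0
            else (patch_odd, patch_match))
    return Trial(
        reference=patch_ref,
        alternatives=alts,
        correct_index=correct_index,
        ref_hypothesis=SpectrumHypothesis.from_nps2d(ref2d, sd, mu, "reference"),
        alt_hypothesis=SpectrumHypothesis.from_nps2d(alt2d, sd, mu, "offset"),
        offset_vector=vec,
    )


@dataclass(frozen=True)
class StaircaseResult:
    """Outcome of one staircase repetition."""

    estimate: float
    trials: list
    reversal_offsets: list
    flags: frozenset

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _aggregate(state: StaircaseState) -> tuple[float, set]:
    cfg = state.config
    flags: set = set()
    used = state.reversal_offsets[-cfg.reversals_used:]
    if len(used) < cfg.reversals_used:
        flags.add("insufficient_reversals")
    if len(state.trials) >= cfg.max_trials:
        flags.add("max_trials_guard")
        if not state.ever_stepped_up:
            flags.add("floor_hit")
    if not used:
        return math.nan, flags
    if cfg.reversal_aggregation == "trials_between":
        first_used = state.reversal_offsets[-len(used)]
        start = next(i for i, t in enumerate(state.trials)
                     if t.reversal and t.offset == first_used)
        vals = [t.offset for t in state.trials[start:]]
    else:
        vals = used
    if state.ceiling_hits >= 5:
        # the infeasible-offset cap was hit persistently: the observer would
        # have needed a larger difference than the parameter space allows
        flags.add("no_threshold")
    return float(np.exp(np.mean(np.log(vals)))), flags


def run_staircase(config: StaircaseConfig, ref, direction: Direction,
                  observer, seed, *, grid_size: int = 128,
                  pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM,
                  mu: float = 0.0, sd: float = 25.0,
                  cache: _NPSCache | None = None) -> StaircaseResult:
    """Run one staircase repetition and return its 80%-point estimate.

    Psychometric-style observers (anything exposing ``p_correct``) are run
    abstractly — each response is a Bernoulli draw from the observer's
    psychometric function, seeded by this run's seed, with no patches
    synthesized.  Ideal observers get fully synthesized trials and decide
    from the LLR.
    """
    rng = np.random.default_rng(seed)
    max_off = max_feasible_offset(ref, direction,
                                  pixel_spacing_cm=pixel_spacing_cm)
    state = StaircaseState(config=config,
                           offset=min(config.start_offset, max_off),
                           max_offset=max_off)
    abstract = hasattr(observer, "p_correct")
    cache = cache or _NPSCache(grid_size, pixel_spacing_cm)
    while not state.done:
        vec = state.offset * direction.vector
        if abstract:
            correct = bool(rng.random() < observer.p_correct(vec))
        else:
            trial_seed = int(rng.integers(2 ** 31))
            trial = make_trial(ref, direction, state.offset, trial_seed,
                               grid_size=grid_size,
                               pixel_spacing_cm=pixel_spacing_cm,
                               mu=mu, sd=sd, cache=cache)
            choice = decide_2afc(trial.ref_hypothesis, *trial.alternatives,
                                 trial.alt_hypothesis, observer,
                                 correct_index=trial.correct_index,
                                 offset_vector=trial.offset_vector)
            correct = choice == trial.correct_index
        staircase_update(state, correct)
    estimate, flags = _aggregate(state)
    return StaircaseResult(estimate=estimate, trials=state.trials,
                           reversal_offsets=list(state.reversal_offsets),
                           flags=frozenset(flags))


@dataclass(frozen=True)
class DirectionThreshold:
    direction: Direction
    threshold: float
    d_fpeak: float
    d_sigma: float
    repetition_estimates: tuple
    flags: frozenset


@dataclass(frozen=True)
class ExperimentResult:
    reference: tuple
    thresholds: tuple

    def points(self) -> np.ndarray:
        """Absolute (f_peak, sigma) threshold points, one per direction."""
        fp, sg = self.reference
        return np.array([[fp + t.d_fpeak, sg + t.d_sigma]
                         for t in self.thresholds])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([
            {"direction": t.direction.index,
             "d_fpeak_lp_per_cm": t.d_fpeak,
             "d_sigma_lp_per_cm": t.d_sigma,
             "threshold_magnitude": t.threshold,
             "flags": ";".join(sorted(t.flags))}
            for t in self.thresholds])


def run_experiment(config: StaircaseConfig, ref, directions, observer,
                   master_seed, *, grid_size: int = 128,
                   pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM,
                   mu: float = 0.0, sd: float = 25.0) -> ExperimentResult:
    """Run the full experiment: all directions, all repetitions.

    The first repetition of each direction is treated as practice and
    discarded; the arithmetic mean of the last ``repetitions_used``
    per-repetition estimates is the direction's threshold, reported both as a
    magnitude and as its (Delta f_peak, Delta sigma) components.
    """
    fp, sg = _ref_params(ref)
    cache = _NPSCache(grid_size, pixel_spacing_cm)
    out = []
    for direction in directions:
        estimates = []
        flags: set = set()
        for rep in range(config.repetitions):
            seed = np.random.SeedSequence(
                [int(master_seed), direction.index, rep])
            res = run_staircase(config, (fp, sg), direction, observer, seed,
                                grid_size=grid_size,
                                pixel_spacing_cm=pixel_spacing_cm,
                                mu=mu, sd=sd, cache=cache)
            estimates.append(res.estimate)
            flags |= set(res.flags)
        used = estimates[-config.repetitions_used:]
        thr = float(np.mean(used))
        out.append(DirectionThreshold(
            direction=direction, threshold=thr,
            d_fpeak=thr * direction.u_fpeak, d_sigma=thr * direction.u_sigma,
            repetition_estimates=tuple(estimates), flags=frozenset(flags)))
    return ExperimentResult(reference=(fp, sg), thresholds=tuple(out))
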