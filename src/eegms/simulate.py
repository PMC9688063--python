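"""Synthetic resting-state EEG cohorts with known microstate ground truth.

The generator emulates the canonical resting-state picture: the scalp
potential field dwells in one of four quasi-stable topographies (microstates
A-D) for tens of milliseconds at a time, then switches abruptly. A cohort
consists of two groups ("HC" and "SZ") whose per-state occurrence weights,
mean dwell times and field-power scales default to values calibrated to
published group statistics for healthy controls versus schizophrenia
patients (e.g. strongly reduced occurrence and coverage of microstate C and
longer microstate D dwell times in the SZ-like group).

Generative model
----------------
1.  A semi-Markov state sequence: run states are drawn from per-state
    occurrence weights with self-transitions forbidden; run lengths are
    gamma distributed around the state's mean duration.
2.  The multichannel signal is ``template[state(t)] * a(t)`` where the
    amplitude envelope ``a(t)`` is a rectified sinusoid (default 10 Hz), so
    global field power (GFP) peaks occur every ~50 ms and each run at
    realistic dwell times contains GFP peaks carrying its template.
3.  Spatially white Gaussian noise, re-referenced to zero channel mean, is
    added so the average-reference invariant of the clean signal survives.

Everything is deterministic given the master seed: per-subject generators
are spawned from ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, standard_1020
from .recording import Recording

__all__ = [
    "STATES",
    "GroupParams",
    "GeneratorConfig",
    "GroundTruth",
    "make_templates",
    "sample_state_sequence",
    "synthesize_recording",
    "generate_cohort",
]

#: Canonical microstate labels, in template-row order.
STATES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class GroupParams:
    """Per-group microstate dynamics parameters (one value per state A-D).

    ``occurrence_weight`` are relative run frequencies (normalized to sum
    to 1); ``mean_duration_ms`` are mean dwell times; ``duration_shape`` is
    the gamma shape parameter controlling dwell-time dispersion
    (CV = 1/sqrt(shape)); ``gfp_scale`` is the GFP, in microvolts, reached
    at the amplitude-envelope maxima of each state; ``noise_sd`` is the
    per-channel additive noise standard deviation in microvolts.
    """

    occurrence_weight: tuple[float, float, float, float]
    mean_duration_ms: tuple[float, float, float, float]
    gfp_scale: tuple[float, float, float, float]
    duration_shape: float = 8.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        w = np.asarray(self.occurrence_weight, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("occurrence weights must be >= 0 with a positive sum")
        if np.count_nonzero(w) < 2:
            raise ValueError(
                "at least two states need positive weight: self-transitions "
                "are forbidden, so a single-state chain is ill-posed"
            )
        object.__setattr__(
            self, "occurrence_weight", tuple(w / w.sum())
        )
        if np.any(np.asarray(self.mean_duration_ms) <= 0):
            raise ValueError("mean durations must be positive")
        if self.duration_shape <= 0 or self.noise_sd < 0:
            raise ValueError("duration_shape must be > 0 and noise_sd >= 0")

    def expected_occurrence_hz(self) -> np.ndarray:
        """Implied per-state occurrence rate (runs per second).

        With run frequencies ``w`` and mean dwell times ``mu`` (ms), one
        second contains ``1000 / sum(w * mu)`` runs, of which a fraction
        ``w_s`` belongs to state ``s``.
        """
        w = np.asarray(self.occurrence_weight)
        mu = np.asarray(self.mean_duration_ms)
        return 1000.0 * w / float(w @ mu)


def _default_groups() -> dict[str, GroupParams]:
    # Occurrence weights proportional to published occurrence rates (Hz);
    # durations (ms) and GFP scales (uV) taken from the same group tables.
    hc = GroupParams(
        occurrence_weight=(3.65, 4.26, 4.13, 4.01),
        mean_duration_ms=(67.18, 58.46, 55.91, 65.07),
        gfp_scale=(4.61, 4.92, 5.20, 5.40),
        noise_sd=0.5,
    )
    sz = GroupParams(
        occurrence_weight=(4.05, 4.41, 2.34, 4.49),
        mean_duration_ms=(56.22, 59.49, 57.29, 79.79),
        gfp_scale=(4.90, 5.05, 5.42, 5.61),
        noise_sd=0.8,  # noisier topographies -> lower map correlations
    )
    return {"HC": hc, "SZ": sz}


@dataclass
class GeneratorConfig:
    """Cohort-level configuration for the synthetic EEG generator.

    Beyond the per-group dynamics parameters, two nuisance-variability
    knobs emulate real resting-state cohorts: ``amp_cv``/``amp_tau``
    impose a slow log-normal drift of the overall field amplitude
    (vigilance-like, unit mean, coefficient of variation ``amp_cv``,
    AR(1) time constant ``amp_tau`` seconds), and ``subject_cv`` draws
    per-subject log-normal jitter of each state's mean duration,
    occurrence weight and GFP scale around the group values
    (between-subject heterogeneity). Set both to 0 for the bare forward
    model.
    """

    n_per_group: int = 14
    fs: float = 250.0
    duration: float = 900.0
    envelope_freq: float = 16.0
    carrier: str = "sine"
    amp_cv: float = 0.4
    amp_tau: float = 5.0
    subject_cv: float = 0.15
    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    montage: Montage = field(default_factory=standard_1020)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 2.0 * self.envelope_freq:
            raise ValueError("fs must exceed twice the envelope frequency")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class GroundTruth:
    """What the generator actually did for one subject."""

    state_sequence: np.ndarray = field(repr=False)  # int codes into STATES
    templates: np.ndarray = field(repr=False)  # (4, n_channels)
    group: str = ""
    params: GroupParams | None = None
    seed: int | None = None

    def labels(self) -> np.ndarray:
        """Per-sample labels as letters A-D."""
        return np.array(STATES)[self.state_sequence]


def _unit_map(m: np.ndarray) -> np.ndarray:
    m = m - m.mean()
    n = np.linalg.norm(m)
    if n == 0:
        raise ValueError("degenerate (constant) template")
    return m / n


def make_templates(
    montage: Montage | None = None, seed: int | None = None
) -> np.ndarray:
    """Four average-referenced, unit-norm ground-truth topographies.

    The maps realize the classic qualitative gradients: A right-frontal /
    left-posterior, B left-frontal / right-posterior, C a midline
    anterior-posterior gradient, D a frontal-midline focal map (built as a
    Gaussian bump with the anterior-posterior gradient projected out so it
    stays distinguishable from C). Pairwise absolute spatial correlations
    are <= 0.7 on the default montage.

    The construction is a deterministic function of the montage; ``seed``
    is accepted for interface symmetry with the samplers and is unused.

    Returns
    -------
    ndarray of shape ``(4, n_channels)``, rows ordered A, B, C, D.
    """
    del seed
    if montage is None:
        montage = standard_1020()
    if montage.n_channels < 4:
        raise ValueError("montage must have at least 4 channels")
    x, y = montage.positions[:, 0], montage.positions[:, 1]
    a = _unit_map(x + 0.7 * y)
    b = _unit_map(-x + 0.7 * y)
    c = _unit_map(y)
    bump = np.exp(-((x**2 + (y - 0.5) ** 2) / (2 * 0.35**2)))
    bump = bump - bump.mean()
    d = _unit_map(bump - (bump @ c) * c)
    return np.vstack([a, b, c, d])


def _chain_weights(w: np.ndarray) -> np.ndarray:
    """Transition weights whose no-self-transition chain realizes ``w``.

    For the chain ``P(i -> j) = v_j / (1 - v_i)`` (``j != i``), the
    stationary run-type frequencies are not ``v``: excluding the current
    state boosts rare states. Requiring stationary frequencies ``w`` gives
    ``S v^2 - S v + w = 0`` per state with ``S = sum_i w_i / (1 - v_i)``,
    solved here by fixed-point iteration on ``S``.
    """
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    if w.size == 2:  # alternation is forced; weights are irrelevant
        return w.copy()
    v = w.copy()
    for _ in range(200):
        s = float(np.sum(w / (1.0 - v)))
        disc = np.maximum(s * s - 4.0 * s * w, 0.0)
        v_new = (s - np.sqrt(disc)) / (2.0 * s)
        if np.max(np.abs(v_new - v)) < 1e-14:
            v = v_new
            break
        v = v_new
    return v


def sample_state_sequence(
    config: GeneratorConfig,
    group: str,
    seed: int | np.random.Generator,
    params: GroupParams | None = None,
) -> np.ndarray:
    """Sample one subject's per-sample microstate sequence.

    Run states follow a no-self-transition Markov chain whose stationary
    run frequencies equal the occurrence weights exactly (the naive
    renormalize-and-exclude chain over-samples rare states; see
    :func:`_chain_weights`). Run lengths are gamma distributed around the state's mean
    duration and then quantized to an integer number of amplitude-envelope
    half-cycles (``1 / (2 * envelope_freq)`` seconds, with stochastic
    rounding so the configured mean is preserved): every state switch then
    falls on a zero-crossing of the carrier, where the field amplitude
    vanishes, and every dwell contains at least one GFP peak. Runs are
    generated until the recording is covered; the last is truncated.

    Returns integer codes into :data:`STATES`, length ``config.n_samples``.
    """
    params = params if params is not None else config.groups[group]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w = np.asarray(params.occurrence_weight)
    mu = np.asarray(params.mean_duration_ms)
    shape = params.duration_shape
    n_total = config.n_samples
    states = np.flatnonzero(w > 0)
    v = _chain_weights(w[states])
    lobe_ms = 1000.0 / (2.0 * config.envelope_freq)

    lobes: list[tuple[int, int]] = []  # (state, n_lobes)
    covered_ms = 0.0
    total_ms = 1000.0 * n_total / config.fs
    current = -1
    while covered_ms < total_ms + lobe_ms:
        if current < 0:
            probs = w[states]
        else:
            probs = v.copy()
            probs[states == current] = 0.0
        probs = probs / probs.sum()
        current = int(rng.choice(states, p=probs))
        dur_ms = rng.gamma(shape, mu[current] / shape)
        frac, whole = np.modf(dur_ms / lobe_ms)
        n_lobes = max(1, int(whole) + int(rng.random() < frac))
        lobes.append((current, n_lobes))
        covered_ms += n_lobes * lobe_ms

    # expand: sample i belongs to lobe floor(t_i / lobe) of the run tiling
    lobe_states = np.concatenate(
        [np.full(n, s, dtype=np.int8) for s, n in lobes]
    )
    t_ms = 1000.0 * np.arange(n_total) / config.fs
    idx = np.minimum((t_ms / lobe_ms).astype(int), len(lobe_states) - 1)
    return lobe_states[idx]


def synthesize_recording(
    sequence: np.ndarray,
    templates: np.ndarray,
    config: GeneratorConfig,
    group: str,
    seed: int | np.random.Generator,
    subject_id: str = "subj",
    params: GroupParams | None = None,
) -> tuple[Recording, GroundTruth]:
    """Render a state sequence into a multichannel recording.

    ``signal[:, t] = sqrt(N) * gfp_scale[s(t)] * a(t) * template[s(t)]``
    where the amplitude ``a(t)`` is the 10/20-band carrier
    ``sin(2 pi f_env t)`` (``config.carrier = "sine"``, the default, whose
    spectrum lies inside the analysis pass band) or its rectified form
    (``"rectified"``). Either way the GFP envelope is the rectified
    sinusoid ``gfp_scale * |sin|``: noise-free, the GFP at envelope maxima
    inside a state's runs equals that state's configured GFP scale, and
    the topography at every GFP peak is a scalar multiple of the active
    template (a positive multiple under the rectified carrier).
    Re-referenced Gaussian noise is then added.
    """
    sequence = np.asarray(sequence)
    templates = np.asarray(templates, dtype=float)
    n_ch = config.montage.n_channels
    if templates.shape[1] != n_ch:
        raise ValueError("template channel count does not match montage")
    if sequence.max() >= templates.shape[0]:
        raise ValueError("sequence alphabet exceeds available templates")
    params = params if params is not None else config.groups[group]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    t = np.arange(sequence.size) / config.fs
    carrier = np.sin(2 * np.pi * config.envelope_freq * t)
    envelope = np.abs(carrier) if config.carrier == "rectified" else carrier
    scale = np.asarray(params.gfp_scale)[sequence]
    amp = np.sqrt(n_ch) * scale * envelope
    if config.amp_cv > 0:
        # slow log-normal vigilance drift: unit mean, CV = amp_cv,
        # AR(1)-smoothed with time constant amp_tau seconds
        from scipy.signal import lfilter

        alpha = np.exp(-1.0 / (config.fs * config.amp_tau))
        eps = rng.normal(size=sequence.size + 1)
        z = lfilter(
            [np.sqrt(1 - alpha**2)], [1.0, -alpha], eps[1:],
            zi=[alpha * eps[0]],  # start at the stationary distribution
        )[0]
        sigma = np.sqrt(np.log1p(config.amp_cv**2))
        amp = amp * np.exp(sigma * z - 0.5 * sigma**2)
    data = templates[sequence].T * amp  # (n_ch, n_samples)

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=data.shape)
        noise -= noise.mean(axis=0, keepdims=True)  # keep average reference
        data = data + noise

    rec = Recording(
        data=data, fs=config.fs, montage=config.montage,
        subject_id=subject_id, group=group,
    )
    gt = GroundTruth(
        state_sequence=sequence, templates=templates, group=group,
        params=params,
    )
    return rec, gt


def generate_cohort(
    config: GeneratorConfig,
) -> list[tuple[Recording, GroundTruth]]:
    """Generate the full two-group cohort, deterministically in the seed.

    Subject streams are spawned from ``SeedSequence(config.seed)`` so any
    subject's data is reproducible independently of the others.
    """
    templates = make_templates(config.montage)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * config.n_per_group)
    cohort: list[tuple[Recording, GroundTruth]] = []
    i = 0
    for group in sorted(config.groups):
        for k in range(config.n_per_group):
            rng = np.random.default_rng(children[i])
            params = _subject_params(config.groups[group], config.subject_cv, rng)
            seq = sample_state_sequence(config, group, rng, params=params)
            rec, gt = synthesize_recording(
                seq, templates, config, group, rng,
                subject_id=f"{group}{k + 1:02d}", params=params,
            )
            gt.seed = config.seed
            cohort.append((rec, gt))
            i += 1
    return cohort


def _subject_params(
    group: GroupParams, cv: float, rng: np.random.Generator
) -> GroupParams:
    """Per-subject heterogeneity: unit-mean log-normal jitter (CV ``cv``)
    on each state's mean duration and occurrence weight. Amplitude
    heterogeneity is left to the slow drift (``amp_cv``), which already
    spreads per-subject mean GFP."""
    if cv <= 0:
        return group

    def jit(values):
        sigma = np.sqrt(np.log1p(cv**2))
        f = np.exp(rng.normal(0.0, sigma, size=len(values)) - 0.5 * sigma**2)
        return tuple(np.asarray(values) * f)

    return GroupParams(
        occurrence_weight=jit(group.occurrence_weight),
        mean_duration_ms=jit(group.mean_duration_ms),
        gfp_scale=group.gfp_scale,
        duration_shape=group.duration_shape,
        noise_sd=group.noise_sd,
    )
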