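"""Generalization experiments and the psychophysics analysis path.

Three drivers build on the probing machinery:

* the within-category experiment slides a narrow training band from the
  left to the right border of each category and traces the error rate
  of heads trained on multi-word stimuli at each step;
* the colored-objects experiment assigns 14 outline-shape classes to 14
  hue bands (two per category) and measures, per class, accuracy as the
  fill color sweeps the whole spectrum;
* the observer analysis reduces match-to-sample response tables (35
  target hues x 35 choice-set shifts) to transition counts with the
  same border machinery used for network rows, plus a bootstrap test of
  inter-observer alignment and a configurable observer simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import borders as _borders
from . import probes as _probes
from . import stimuli as _stimuli
from .colorspace import HueBand, bin_centers, circular_distance
from .evolution import BorderSet
from .probes import ResponderModel, category_of

__all__ = [
    "ErrorCurve",
    "within_category_error_curve",
    "place_14_bands",
    "ObjectExperimentResult",
    "object_color_experiment",
    "ObserverTable",
    "simulate_observer",
    "observer_transition_analysis",
    "bootstrap_correlation_test",
]


# ---------------------------------------------------------------------------
# within-category band shifting


@dataclass
class ErrorCurve:
    """Error rates as training bands slide across each category.

    ``errors`` has shape (n_categories, n_steps, n_repetitions).
    ``positions`` holds each step's band-center offset as a fraction of
    the category span (0 = left border, 1 = right border).
    """

    positions: np.ndarray
    errors: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.errors.mean(axis=2)

    @property
    def sd(self) -> np.ndarray:
        return self.errors.std(axis=2)


def _step_bands(border_positions: np.ndarray, step_frac: float,
                band_frac: float = 0.10):
    """One training band per category, centered at ``step_frac`` of its span."""
    pos = np.asarray(border_positions)
    spans = (np.roll(pos, -1) - pos) % 1.0
    bands = []
    for left, s in zip(pos, spans):
        center = (left + step_frac * s) % 1.0
        bands.append(HueBand(center, band_frac * s / 2.0))
    return bands


def within_category_error_curve(
    extractor_or_responder,
    border_estimate,
    n_steps: int = 10,
    n_repetitions: int = 15,
    n_bins: int = 100,
    band_frac: float = 0.10,
    train_cfg: _probes.TrainConfig | None = None,
    samples_per_bin: int = 20,
    seed: int = 0,
) -> ErrorCurve:
    """Train heads on sliding within-category bands; measure their error.

    For step ``j`` the 7 training bands (width ``band_frac`` of each
    category span) are centered at ``j/(n_steps-1)`` of the span, so the
    first and last steps sit on the borders themselves.  Heads are
    trained on multi-word stimuli and evaluated on the spectrum bins
    whose centers fall inside each training band; a responder stands in
    for train+evaluate when given.
    """
    pos = np.sort(np.asarray(getattr(border_estimate, "positions", border_estimate),
                             dtype=float) % 1.0)
    n_cat = len(pos)
    spans = (np.roll(pos, -1) - pos) % 1.0
    train_cfg = train_cfg or _probes.TrainConfig(n_train_per_class=100,
                                                 n_val_per_class=20, epochs=5)
    centers = bin_centers(n_bins)
    step_fracs = np.linspace(0.0, 1.0, n_steps)
    errors = np.empty((n_cat, n_steps, n_repetitions))
    is_responder = isinstance(extractor_or_responder, ResponderModel)
    for j, frac in enumerate(step_fracs):
        bands = _step_bands(pos, frac, band_frac)

        class _Bands:
            n_classes = n_cat

        _Bands.bands = bands
        _Bands.centers = np.array([b.center for b in bands])
        for r in range(n_repetitions):
            rng = np.random.default_rng(np.random.SeedSequence([seed, j, r]))
            if is_responder:
                row = _probes.simulate_row(
                    extractor_or_responder, _Bands(),
                    _probes.EvalGrid(n_bins, samples_per_bin), rng,
                )
                predictions = row.samples
            else:
                head = _probes.train_probe_head(
                    extractor_or_responder, _Bands(), train_cfg, rng,
                    stimulus_fn=lambda h, c, g: _stimuli.render_multiword_stimulus(h, c, g),
                )
                row = _probes.evaluate_spectrum(
                    head, extractor_or_responder,
                    _probes.EvalGrid(n_bins, samples_per_bin), rng,
                    stimulus_fn=lambda h, c, g: _stimuli.render_multiword_stimulus(h, c, g),
                )
                predictions = row.samples
            for cls, band in enumerate(bands):
                member = band.contains(centers)
                if not member.any():  # band narrower than one bin
                    member = np.zeros(n_bins, bool)
                    member[np.argmin(circular_distance(centers, band.center))] = True
                errors[cls, j, r] = float(np.mean(predictions[member] != cls))
    return ErrorCurve(positions=step_fracs, errors=errors)


# ---------------------------------------------------------------------------
# colored objects


def place_14_bands(border_estimate) -> list:
    """Two bands per category: centers of its left and right halves.

    Each band's width is 1/5 of its category span, so for any valid
    border set the 14 bands are pairwise disjoint.
    """
    pos = np.sort(np.asarray(getattr(border_estimate, "positions", border_estimate),
                             dtype=float) % 1.0)
    spans = (np.roll(pos, -1) - pos) % 1.0
    bands = []
    for left, s in zip(pos, spans):
        hw = s / 10.0  # width s/5
        bands.append(HueBand((left + s / 4.0) % 1.0, hw))
        bands.append(HueBand((left + 3.0 * s / 4.0) % 1.0, hw))
    return bands


@dataclass
class ObjectExperimentResult:
    """Accuracy per band as the fill hue sweeps the spectrum.

    ``accuracy`` has shape (n_permutations, 14, n_bins): per run, per
    trained class (aligned with the band order), the proportion of
    held-out drawings classified to that class at each fill hue.
    """

    bands: list
    accuracy: np.ndarray

    @property
    def median(self) -> np.ndarray:
        return np.median(self.accuracy, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.accuracy.std(axis=0)


def object_color_experiment(
    extractor,
    border_estimate,
    shape_families=_stimuli.OUTLINE_FAMILIES,
    n_permutations: int = 100,
    n_train_per_class: int = 500,
    n_val_per_class: int = 50,
    n_eval_outlines: int = 80,
    n_bins: int = 100,
    train_cfg_epochs: int = 5,
    seed: int = 0,
) -> ObjectExperimentResult:
    """Train on 14 colored object classes; evaluate over the full spectrum.

    Per permutation, the shape families are shuffled onto the 14 bands,
    a probe head is trained on enclosure-filled outlines whose fill
    hues come from each class's band, and each class is then evaluated
    on held-out outlines filled at every spectrum bin center.
    """
    bands = place_14_bands(border_estimate)
    families = list(shape_families)
    if len(families) != len(bands):
        raise ValueError(f"need {len(bands)} shape families, got {len(families)}")
    n_classes = len(bands)
    centers = bin_centers(n_bins)
    accuracy = np.empty((n_permutations, n_classes, n_bins))
    for perm_i in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, perm_i]))
        order = rng.permutation(n_classes)
        assigned = [families[o] for o in order]

        # held-out evaluation outlines are generated after (hence disjoint
        # from) the training/validation outlines for each class
        def render_class_batch(cls, n):
            fam = assigned[cls]
            imgs = []
            for _ in range(n):
                outline = _stimuli.generate_synthetic_outline(fam, rng)
                imgs.append(_stimuli.render_filled_shape(outline, float(bands[cls].sample(rng))))
            return np.stack(imgs)

        xs, ys = [], []
        for cls in range(n_classes):
            xs.append(extractor.extract(render_class_batch(cls, n_train_per_class)))
            ys.append(np.full(n_train_per_class, cls))
        xtr = np.concatenate(xs)
        ytr = np.concatenate(ys)
        xs, ys = [], []
        for cls in range(n_classes):
            xs.append(extractor.extract(render_class_batch(cls, n_val_per_class)))
            ys.append(np.full(n_val_per_class, cls))
        xva = np.concatenate(xs)
        yva = np.concatenate(ys)
        mean = xtr.mean(axis=0)
        sd = xtr.std(axis=0) + 1e-6
        w, b, _, _ = _probes._softmax_sgd(
            (xtr - mean) / sd, ytr, (xva - mean) / sd, yva,
            n_classes, train_cfg_epochs, 64, 0.2, rng,
        )
        head = _probes.ProbeHead(weights=w, bias=b, feat_mean=mean, feat_sd=sd,
                                 trained=True)
        for cls in range(n_classes):
            fam = assigned[cls]
            outlines = [_stimuli.generate_synthetic_outline(fam, rng)
                        for _ in range(n_eval_outlines)]
            for bi, hue in enumerate(centers):
                imgs = np.stack([
                    _stimuli.render_filled_shape(o, float(hue)) for o in outlines
                ])
                pred = head.predict(extractor.extract(imgs))
                accuracy[perm_i, cls, bi] = float(np.mean(pred == cls))
    return ObjectExperimentResult(bands=bands, accuracy=accuracy)


# ---------------------------------------------------------------------------
# psychophysics


@dataclass
class ObserverTable:
    """Complete match-to-sample grid: 35 target hues x 35 choice-set shifts.

    ``choices[t, s]`` is the chosen class index (0..6) when the target
    hue is ``(t + 0.5)/35`` and the 7 choice hues are
    ``(k/7 + s/35) mod 1``.
    """

    choices: np.ndarray
    observer_id: str = "sim"
    n_choices: int = 7

    def __post_init__(self):
        self.choices = np.asarray(self.choices)
        if self.choices.shape[0] != self.choices.shape[1]:
            raise ValueError("observer table must be square")
        bad = (self.choices < 0) | (self.choices >= self.n_choices)
        if bad.any():
            t, s = np.argwhere(bad)[0]
            raise ValueError(f"invalid/missing choice at target {t}, shift {s}")

    @property
    def n_steps(self) -> int:
        return int(self.choices.shape[0])

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)

    def to_frame(self) -> pd.DataFrame:
        t, s = np.meshgrid(np.arange(self.n_steps), np.arange(self.n_steps),
                           indexing="ij")
        return pd.DataFrame({
            "target_hue_index": t.ravel(),
            "shift_index": s.ravel(),
            "choice_index": self.choices.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, observer_id: str = "obs",
                   n_steps: int = 35) -> "ObserverTable":
        grid = np.full((n_steps, n_steps), -1, dtype=int)
        for _, row in df.iterrows():
            grid[int(row.target_hue_index), int(row.shift_index)] = int(row.choice_index)
        return cls(choices=grid, observer_id=observer_id)


def simulate_observer(
    planted: BorderSet | np.ndarray,
    rng: np.random.Generator,
    lapse_rate: float = 0.0,
    border_jitter_sd: float = 0.0,
    n_steps: int = 35,
    n_choices: int = 7,
    observer_id: str = "sim",
) -> ObserverTable:
    """Simulated categorical observer on the match-to-sample design.

    The observer carries the planted borders, each jittered once by a
    wrapped normal (per-observer perceptual idiosyncrasy).  On each
    trial the choice whose (jittered) category matches the target's is
    selected (nearest-in-hue choice if the category holds several or
    none); with probability ``lapse_rate`` a uniform random choice is
    made instead.
    """
    borders = np.sort(np.asarray(
        planted.as_array() if isinstance(planted, BorderSet) else planted,
        dtype=float) % 1.0)
    jittered = np.sort((borders + rng.normal(0.0, border_jitter_sd, len(borders))) % 1.0) \
        if border_jitter_sd > 0 else borders
    targets = (np.arange(n_steps) + 0.5) / n_steps
    choices = np.empty((n_steps, n_steps), dtype=int)
    for s in range(n_steps):
        choice_hues = (np.arange(n_choices) / n_choices + s / n_steps) % 1.0
        choice_cats = category_of(choice_hues, jittered)
        for t, target in enumerate(targets):
            if lapse_rate > 0 and rng.random() < lapse_rate:
                choices[t, s] = rng.integers(n_choices)
                continue
            cat = int(category_of(target, jittered))
            in_cat = np.nonzero(choice_cats == cat)[0]
            pool = in_cat if len(in_cat) else np.arange(n_choices)
            d = circular_distance(choice_hues[pool], target)
            choices[t, s] = int(pool[np.argmin(d)])
    return ObserverTable(choices=choices, observer_id=observer_id)


def observer_transition_count(table: ObserverTable) -> np.ndarray:
    """Per-target-bin transition counts for one observer (over all rows)."""
    n = table.n_steps
    raw = np.zeros(n, dtype=int)
    for s in range(n):
        seq = table.choices[:, s]
        raw[_borders.find_transitions(seq)] += 1
    return raw


def observer_transition_analysis(
    tables, sigma: float = 1.5, min_separation: int = 2,
    prominence_frac: float = 0.10,
) -> tuple:
    """Accumulate observer transitions; detect borders; compute prototypes.

    The identical transition/peak/prototype machinery used for network
    rows is applied at the psychophysics resolution (35 bins).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no observer tables")
    raw = np.zeros(tables[0].n_steps, dtype=int)
    for tb in tables:
        raw += observer_transition_count(tb)
    tc = _borders.TransitionCount(raw=raw, sigma=sigma)
    est = _borders.detect_peaks(tc, min_separation=min_separation,
                                prominence_frac=prominence_frac)
    protos = _borders.compute_prototypes(est, tc) if est.n_borders >= 2 else None
    return tc, est, protos


def bootstrap_correlation_test(
    tables,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Are observers' transition counts aligned beyond chance?

    The statistic is the mean pairwise Pearson correlation between
    observers' per-bin transition-count vectors.  The null distribution
    is built by independently circularly shifting each observer's
    vector by a uniform random offset per replicate; the p-value is the
    fraction of null statistics at least as large as the observed one.
    """
    import warnings

    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 observers")
    if n_boot < 10:
        raise ValueError("n_boot too small for any inference")
    if n_boot < 1000:
        warnings.warn("n_boot below 1000 gives a coarse p-value", stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng()
    counts = np.stack([
        tb if isinstance(tb, np.ndarray) else observer_transition_count(tb)
        for tb in tables
    ]).astype(float)
    n_obs, n = counts.shape

    def mean_pairwise_corr(mat):
        c = np.corrcoef(mat)
        iu = np.triu_indices(n_obs, k=1)
        return float(np.nanmean(c[iu]))

    observed = mean_pairwise_corr(counts)
    null = np.empty(n_boot)
    for b in range(n_boot):
        offsets = rng.integers(0, n, size=n_obs)
        shifted = np.stack([np.roll(counts[i], offsets[i]) for i in range(n_obs)])
        null[b] = mean_pairwise_corr(shifted)
    p = float(np.mean(null >= observed))
    return {"statistic": observed, "p_value": p, "n_boot": n_boot, "null": null}
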