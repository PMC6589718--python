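"""Synthetic participant populations and miniature fixture datasets.

The default hyperparameters are calibrated so that a convex-transducer cohort
(exponent median ~1.3, transduction threshold 42 C, decision noise ~2.9x the
gain) produces detection thresholds in the 1-4 C range, with
decrease-from-45 thresholds larger than increase-from-45 thresholds but
decrease-from-47 thresholds close to increase-from-45 thresholds — the
qualitative pattern the convex mechanism predicts.  ``null_hyperparams``
freezes the exponent at 1 (linear transducer), under which increase and
decrease detection are exactly symmetric; it backs type-I-error calibration.

Seeding: the cohort is drawn from one substream of the global seed, with one
child stream per participant, so adding a participant never changes the
parameters of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import __version__
from ._rng import block_rng
from .design import preset, run_experiment, run_rating_task
from .observer import ObserverSpec, save_cohort

__all__ = [
    "CohortHyperparams",
    "default_hyperparams",
    "null_hyperparams",
    "generate_cohort",
    "make_fixture_dataset",
    "FIXTURE_PRESETS",
]


@dataclass(frozen=True)
class CohortHyperparams:
    """Population distributions from which individual observers are drawn.

    Log-normal parameters are (median, sd of log); ranges are uniform.
    ``noise_ratio`` is decision noise expressed as a multiple of the gain, so
    discriminability depends on it and the exponent but not on the gain
    itself.
    """

    n_participants: int = 16
    exponent_median: float = 1.3
    exponent_logsd: float = 0.05
    gain_median: float = 1.0
    gain_logsd: float = 0.1
    noise_ratio_median: float = 2.9
    noise_ratio_logsd: float = 0.08
    lapse_range: tuple[float, float] = (0.0, 0.02)
    offset: float = 42.0
    # confidence criteria as multiples of the decision noise
    criteria_scale: tuple[float, float, float] = (0.5, 1.0, 1.8)
    rating_slope_median: float = 0.6
    rating_slope_logsd: float = 0.1
    rating_intercept_mean: float = 0.7
    rating_intercept_sd: float = 0.3
    rating_noise_median: float = 0.8
    rating_noise_logsd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        lo, hi = self.lapse_range
        if not (0.0 <= lo <= hi <= 0.1):
            raise ValueError("lapse_range must satisfy 0 <= lo <= hi <= 0.1")
        if self.exponent_median < 1:
            raise ValueError("exponent_median must be >= 1")
        for name in ("exponent_logsd", "gain_logsd", "noise_ratio_logsd",
                     "rating_slope_logsd", "rating_noise_logsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gain_median <= 0 or self.noise_ratio_median <= 0:
            raise ValueError("gain and noise-ratio medians must be positive")


def default_hyperparams(**overrides) -> CohortHyperparams:
    """Calibrated convex-transducer population (the mechanism cohort)."""
    return replace(CohortHyperparams(), **overrides) if overrides else CohortHyperparams()


def null_hyperparams(**overrides) -> CohortHyperparams:
    """Linear-transducer population: no increase/decrease asymmetry."""
    hp = CohortHyperparams(
        exponent_median=1.0,
        exponent_logsd=0.0,
        noise_ratio_median=1.6,
        noise_ratio_logsd=0.1,
    )
    return replace(hp, **overrides) if overrides else hp


def _lognormal(rng: np.random.Generator, median: float, logsd: float) -> float:
    if logsd == 0:
        return median
    return float(np.exp(np.log(median) + logsd * rng.standard_normal()))


def generate_cohort(hp: CohortHyperparams, seed: int) -> list[ObserverSpec]:
    """Draw ``hp.n_participants`` observers, one RNG substream each."""
    cohort = []
    for pid in range(hp.n_participants):
        rng = block_rng(seed, pid, 0, stream="cohort")
        exponent = max(1.0, _lognormal(rng, hp.exponent_median, hp.exponent_logsd))
        gain = _lognormal(rng, hp.gain_median, hp.gain_logsd)
        noise = gain * _lognormal(rng, hp.noise_ratio_median, hp.noise_ratio_logsd)
        lapse = float(rng.uniform(*hp.lapse_range))
        criteria = tuple(round(s * noise, 6) for s in hp.criteria_scale)
        cohort.append(
            ObserverSpec(
                gain=round(gain, 6),
                exponent=round(exponent, 6),
                offset=hp.offset,
                noise=round(noise, 6),
                lapse=round(lapse, 6),
                confidence_criteria=criteria,
                rating_intercept=round(
                    max(0.0, hp.rating_intercept_mean
                        + hp.rating_intercept_sd * rng.standard_normal()), 6),
                rating_slope=round(
                    _lognormal(rng, hp.rating_slope_median, hp.rating_slope_logsd), 6),
                rating_noise=round(
                    _lognormal(rng, hp.rating_noise_median, hp.rating_noise_logsd), 6),
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

FIXTURE_PRESETS = (
    "exp1_small",
    "exp2_small",
    "exp3_small",
    "rating_small",
    "null_linear",
)

_FIXTURE_N = 6


def make_fixture_dataset(preset_name: str, seed: int, out_dir) -> dict[str, str]:
    """Write a miniature end-to-end dataset (CSV/JSON only) and its manifest.

    Regenerating with the same preset and seed reproduces byte-identical
    files.  Returns a mapping from artifact role to file path.
    """
    if preset_name not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; choose from {FIXTURE_PRESETS}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if preset_name == "null_linear":
        hp = null_hyperparams(n_participants=_FIXTURE_N)
        exp_id = "1"
        config = replace(preset("1"), tasks=("detection",))
    else:
        hp = default_hyperparams(n_participants=_FIXTURE_N)
        exp_id = {"exp1_small": "1", "exp2_small": "2", "exp3_small": "3",
                  "rating_small": "rating"}[preset_name]
        config = preset(exp_id)

    cohort = generate_cohort(hp, seed)
    paths: dict[str, str] = {}
    cohort_path = out / "cohort.json"
    save_cohort(cohort, cohort_path)
    paths["cohort"] = str(cohort_path)

    if exp_id == "rating":
        ratings = run_rating_task(config, cohort, seed)
        ratings_path = out / "ratings.csv"
        ratings.to_csv(ratings_path, index=False)
        paths["ratings"] = str(ratings_path)
    else:
        result = run_experiment(config, cohort, seed)
        result.save(out)
        paths["thresholds"] = str(out / "thresholds.csv")
        paths["blocks"] = str(out / "blocks")

    manifest = {
        "preset": preset_name,
        "seed": seed,
        "n_participants": _FIXTURE_N,
        "hyperparams": asdict(hp),
        "experiment_config": json.loads(config.to_json()),
        "package_version": __version__,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = str(manifest_path)
    return paths
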