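"""Seeded synthetic episode-classification benchmark.

Builds, end to end, everything the evaluation protocol needs from the
generator alone: a training corpus -> KLT model and normalization stds,
one short record per episode -> preprocessing -> delineation -> episode
mean feature vectors for both transforms and all coefficient subsets.
"""

from __future__ import annotations

import numpy as np

from stmorph.basis import lpt_basis
from stmorph.delineate import NormalizationModel, delineate_record
from stmorph.evaluate import EpisodeFeature, SUBSETS, episode_feature
from stmorph.klt import KLTModel, coefficient_stds, train_klt
from stmorph.preprocess import preprocess_record
from stmorph.synth import (
    EpisodeSpec,
    HEART_RATE_RELATED,
    ISCHAEMIC,
    SyntheticRecordConfig,
    make_record,
    make_training_corpus,
)

__all__ = ["train_models", "build_benchmark"]


def train_models(
    seed: int = 0,
    n_intervals: tuple[int, int, int] = (40, 20, 60),
) -> tuple[KLTModel, NormalizationModel]:
    """Train a KLT model and normalization stds on a seeded synthetic corpus."""
    corpus = make_training_corpus(*n_intervals, seed=seed)
    klt = train_klt(corpus)
    pooled = np.vstack([patterns for _, patterns in corpus])
    theta = coefficient_stds(pooled, lpt_basis(klt.basis.M))
    norm = NormalizationModel(
        rho=klt.stds,
        theta=theta,
        provenance=f"synthetic corpus seed={seed} intervals={n_intervals}",
    )
    return klt, norm


def _episode_config(kind: str, rng: np.random.Generator, seed: int) -> SyntheticRecordConfig:
    onset = 15.0
    extremum = rng.uniform(35.0, 45.0)
    offset = rng.uniform(62.0, 70.0)
    if kind == ISCHAEMIC:
        sign = -1.0 if rng.random() < 0.7 else 1.0
        spec = EpisodeSpec(
            kind=ISCHAEMIC,
            onset_s=onset,
            extremum_s=extremum,
            offset_s=offset,
            extremum_magnitude=sign * rng.uniform(80.0, 250.0),
            hr_delta=rng.uniform(0.0, 10.0),
            affected_leads=(0,),
            slope_factor=rng.uniform(0.0, 0.3),
            scoop_factor=rng.uniform(0.2, 0.5),
        )
    else:
        spec = EpisodeSpec(
            kind=HEART_RATE_RELATED,
            onset_s=onset,
            extremum_s=extremum,
            offset_s=offset,
            hr_delta=rng.uniform(25.0, 55.0),
            affected_leads=(0,),
        )
    return SyntheticRecordConfig(
        duration_s=80.0,
        leads=1,
        base_hr=rng.uniform(60.0, 80.0),
        episodes=[spec],
        noise_rms=10.0,
        baseline_wander=(rng.uniform(40.0, 120.0), 0.3),
        seed=seed,
    )


def build_benchmark(
    n_ischaemic: int = 200,
    n_hr_related: int = 100,
    seed: int = 0,
) -> dict[tuple[str, str], list[EpisodeFeature]]:
    """Episode feature sets keyed by (transform, subset) for a seeded benchmark."""
    klt, norm = train_models(seed=seed)
    lpt = lpt_basis(klt.basis.M)
    rng = np.random.default_rng(seed + 1)

    features: dict[tuple[str, str], list[EpisodeFeature]] = {
        (t, s): [] for t in ("KLT", "LPT") for s in SUBSETS
    }
    kinds = [ISCHAEMIC] * n_ischaemic + [HEART_RATE_RELATED] * n_hr_related
    for i, kind in enumerate(kinds):
        config = _episode_config(kind, rng, seed=seed + 1000 + i)
        record, episodes, _ = make_record(config)
        clean = preprocess_record(record)
        series = delineate_record(clean, lpt, klt, norm)
        for transform in ("KLT", "LPT"):
            for subset in SUBSETS:
                feat = episode_feature(series, episodes[0], transform, subset)
                if feat is not None:
                    features[(transform, subset)].append(feat)
    return features
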