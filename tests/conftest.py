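"""Shared fixtures: tiny hand-built annotations and experiments."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from regnorm.core import (
    ExperimentSet,
    ProbeAnnotation,
    ProbeCategory,
    TwoChannelArray,
)

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_annotation(
    n: int = 6,
    chrom: str = "chr1",
    spacing: int = 100,
    length: int = 50,
    categories: list[ProbeCategory] | None = None,
) -> ProbeAnnotation:
    if categories is None:
        categories = [ProbeCategory.TILING] * n
    return ProbeAnnotation(
        probe_id=np.array([f"P{i:04d}" for i in range(n)], dtype=object),
        chrom=np.array([chrom] * n, dtype=object),
        position=np.arange(n, dtype=np.int64) * spacing,
        probe_length=np.full(n, length, dtype=np.int64),
        category=np.array(categories, dtype=object),
    )


def make_experiment(
    greens: list[np.ndarray], reds: list[np.ndarray], annotation=None
) -> ExperimentSet:
    n = len(greens[0])
    if annotation is None:
        annotation = make_annotation(n)
    arrays = [
        TwoChannelArray(f"array{j + 1:02d}", green=np.asarray(g, float), red=np.asarray(r, float))
        for j, (g, r) in enumerate(zip(greens, reds))
    ]
    return ExperimentSet(annotation=annotation, arrays=arrays)


@pytest.fixture
def tiny_annotation() -> ProbeAnnotation:
    return make_annotation(3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
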