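"""Long-series registration by splitting into overlapping short series.

Structural regression relies on the cylinder approximation of neurites,
which only holds over short spans, so a long stack is divided into n
near-equal short series.  The last section of each short series — the
*benchmark* section — is also the first section of the next one.  The
benchmark sections form a low-axial-resolution series of their own and are
rigidly chained (SIFT+RANSAC pairwise, composed into a global frame), which
fixes the endpoints of every short series; each short series is then
registered and compensated independently and the results are restacked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .descriptors import DescriptorExtractor
from .flow import RigidTransform
from .pairwise import FlowEstimator
from .regression import run_structural_regression
from .serial import register_rigid, sequential_register
from .stack_io import SectionStack

__all__ = [
    "SeriesPartition",
    "split_series",
    "register_benchmark_chain",
    "register_long",
]


@dataclass
class SeriesPartition:
    """Index ranges of the short series within the parent stack.

    ``segments[k] = (start, stop)`` is inclusive of both ends; consecutive
    segments share exactly one index (the benchmark section).
    """

    n_total: int
    segments: list[tuple[int, int]]

    @property
    def benchmark_indices(self) -> list[int]:
        """Every segment boundary, including the outer endpoints."""
        return [s for s, _ in self.segments] + [self.segments[-1][1]]

    @property
    def shared_indices(self) -> list[int]:
        """Benchmarks shared between two consecutive segments."""
        return [s for s, _ in self.segments[1:]]

    def lengths(self) -> list[int]:
        return [stop - start + 1 for start, stop in self.segments]


def split_series(n_total: int, n_segments: int) -> SeriesPartition:
    """Divide ``n_total`` sections into ``n_segments`` near-equal short
    series sharing single benchmark sections.

    With shared boundaries the segments jointly occupy
    ``n_total + n_segments − 1`` slots; the base length is that total
    divided by ``n_segments`` and earlier segments take one extra slot
    each until the remainder is spent (deterministic rule).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    slots = n_total + n_segments - 1
    base, rem = divmod(slots, n_segments)
    if base < 3:
        raise ValueError(
            f"cannot split {n_total} sections into {n_segments} segments of length >= 3"
        )
    segments: list[tuple[int, int]] = []
    start = 0
    for k in range(n_segments):
        length = base + (1 if k < rem else 0)
        stop = start + length - 1
        segments.append((start, stop))
        start = stop  # shared benchmark
    assert segments[-1][1] == n_total - 1
    return SeriesPartition(n_total=n_total, segments=segments)


def register_benchmark_chain(
    benchmarks: SectionStack, seed: int = 0
) -> list[RigidTransform]:
    """Rigidly chain the benchmark sections into the frame of the first one.

    Pairwise transforms T_k (placing benchmark k onto benchmark k−1) are
    estimated by SIFT+RANSAC and composed into global placements
    G_0 = identity, G_k = G_{k−1} ∘ T_k.
    """
    if benchmarks.n < 2:
        raise ValueError("need at least two benchmark sections")
    placements = [RigidTransform()]
    for k in range(1, benchmarks.n):
        try:
            T = register_rigid(benchmarks[k], benchmarks[k - 1], seed=seed)
        except Exception as exc:
            raise RuntimeError(
                f"rigid registration failed between benchmarks {k - 1} and {k}: {exc}"
            ) from exc
        placements.append(placements[-1].compose(T))
    return placements


def register_long(
    stack: SectionStack,
    n_segments: int,
    estimator: FlowEstimator,
    extractor: Optional[DescriptorExtractor] = None,
    chain_seed: int = 0,
    run_regression: bool = True,
) -> tuple[SectionStack, SeriesPartition, list[RigidTransform]]:
    """Register a long stack segment by segment.

    Returns the restacked result (same length as the input), the partition,
    and the benchmark placements.  Each shared benchmark is emitted once, at
    its rigid placement.
    """
    partition = split_series(stack.n, n_segments)
    bench_idx = partition.benchmark_indices
    benchmarks = SectionStack(stack.data[bench_idx].copy())
    placements = register_benchmark_chain(benchmarks, seed=chain_seed)
    out = np.empty_like(stack.data)
    for k, (start, stop) in enumerate(partition.segments):
        sub = SectionStack(stack.data[start : stop + 1].copy())
        result = sequential_register(
            sub,
            estimator,
            endpoint_mode="provided",
            endpoint_rigid=placements[k + 1],
            first_rigid=placements[k],
        )
        final = (
            run_structural_regression(result, extractor=extractor, estimator=estimator)
            if run_regression
            else result.warped
        )
        # the shared benchmark was already written by the previous segment
        # and is identical by construction (rigid placement only)
        lo = start if k == 0 else start + 1
        out[lo : stop + 1] = final.data[(lo - start):]
    return (
        SectionStack(out, pixel_size_nm=stack.pixel_size_nm, thickness_nm=stack.thickness_nm),
        partition,
        placements,
    )
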