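"""Embarrassingly-parallel mapping over local worker processes.

Per-frame kinematics and per-variant perturbation runs are independent
computations, so they can be partitioned into contiguous chunks and
mapped over a process pool.  The contract is strict serial equivalence:
for every worker count the gathered output is bit-for-bit identical to
sequential application in order.  Static calibration is never
parallelized (it averages across frames and is cheap).
"""

from __future__ import annotations

import multiprocessing
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from functools import partial

from .errors import ParallelExecutionError, ValidationError

__all__ = ["ChunkPlan", "plan_chunks", "map_indexed", "map_frames"]


@dataclass(frozen=True)
class ChunkPlan:
    """Contiguous balanced partition of [0, n_items) across workers."""

    n_items: int
    n_workers: int
    ranges: tuple

    def __post_init__(self) -> None:
        covered = 0
        sizes = []
        for start, stop in self.ranges:
            if start != covered or stop < start:
                raise ValidationError("chunk ranges must partition [0, n) in order")
            sizes.append(stop - start)
            covered = stop
        if covered != self.n_items:
            raise ValidationError("chunk ranges must cover [0, n_items) exactly")
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValidationError("chunk sizes may differ by at most one")


def plan_chunks(n_items: int, n_workers: int) -> ChunkPlan:
    """Divide ``n_items`` evenly among ``n_workers`` contiguous ranges.

    More workers than items collapses to one item per worker.
    """
    if n_workers < 1:
        raise ValidationError(f"worker count must be >= 1, got {n_workers}")
    if n_items < 0:
        raise ValidationError(f"item count must be >= 0, got {n_items}")
    eff = min(n_workers, n_items)
    if eff == 0:
        return ChunkPlan(n_items, 0, ())
    base, rem = divmod(n_items, eff)
    ranges = []
    start = 0
    for w in range(eff):
        size = base + (1 if w < rem else 0)
        ranges.append((start, start + size))
        start += size
    return ChunkPlan(n_items, eff, tuple(ranges))


def _run_range(fn, start: int, stop: int) -> list:
    out = []
    for i in range(start, stop):
        try:
            out.append(fn(i))
        except Exception as e:  # noqa: BLE001 - re-raised with context
            raise ParallelExecutionError(
                f"worker failed on item {i} in range [{start}, {stop}): {e}"
            ) from e
    return out


def map_indexed(fn, n_items: int, n_workers: int = 1) -> list:
    """Apply ``fn(i)`` for i in [0, n_items), order preserved.

    ``fn`` must be pure per item and picklable (a module-level function or
    functools.partial of one).  Output is identical for every worker
    count.
    """
    plan = plan_chunks(n_items, n_workers)
    if plan.n_workers <= 1:
        return _run_range(fn, 0, n_items)
    ctx = multiprocessing.get_context("fork")
    results: list = []
    with ProcessPoolExecutor(max_workers=plan.n_workers, mp_context=ctx) as pool:
        futures = [pool.submit(_run_range, fn, start, stop)
                   for start, stop in plan.ranges]
        for (start, stop), fut in zip(plan.ranges, futures):
            try:
                results.extend(fut.result())
            except ParallelExecutionError:
                raise
            except Exception as e:  # worker crashed outside the item loop
                raise ParallelExecutionError(
                    f"worker for range [{start}, {stop}) failed: {e}") from e
    return results


def _frame_item(i: int, trial=None, calib=None, options=None):
    from .cgm_core import frame_kinematics
    return frame_kinematics(trial.frame_markers(i), calib, options=options)


def map_frames(trial, calib, options=None, n_workers: int = 1) -> list:
    """Run per-frame kinematics over a dynamic trial's frames.

    Returns the per-frame records in frame order; bit-identical to the
    serial run for any worker count.
    """
    fn = partial(_frame_item, trial=trial, calib=calib, options=options)
    return map_indexed(fn, trial.n_frames, n_workers)
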