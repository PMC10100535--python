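"""Subtractive QM/MM combination of a high-level and a low-level engine.

The system's degrees of freedom are split into two disjoint regions.  The
low-level engine sees the full system; the high-level engine sees the inner
(QM) region only, and the low-level description of that inner region is
subtracted out:

    E_total = E(full, low) - E(QM, low) + E(QM, high)

with the gradient combined by the same signs, the inner-region gradient terms
scattered onto the QM indices.  Forces are the negative of the combined
gradient.  Mechanical embedding only: the high-level engine never sees the
environment, which enters solely through the low-level full-system term.

Engine contract: a callable ``engine(x, state) -> (energy, gradient)`` where
``x`` is a flat geometry (either the full system or the QM region — a low-level
engine must accept both lengths) and ``state`` an electronic state index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["RegionPartition", "SubtractiveEnergy", "partition_system", "subtractive_energy_and_gradient"]

Engine = Callable[[np.ndarray, int], tuple[float, np.ndarray]]


@dataclass(frozen=True)
class RegionPartition:
    """Validated split of DOF indices into a QM region and its MM complement."""

    qm_indices: np.ndarray
    mm_indices: np.ndarray
    total_dof: int

    @property
    def n_qm(self) -> int:
        return self.qm_indices.size

    def solvent_mask(self) -> np.ndarray:
        """Boolean mask over all DOFs selecting the MM region."""
        mask = np.zeros(self.total_dof, dtype=bool)
        mask[self.mm_indices] = True
        return mask


def partition_system(total_dof: int, qm_indices) -> RegionPartition:
    """Validate and build a two-region partition from an index list."""
    qm = np.asarray(list(qm_indices), dtype=int)
    if qm.size == 0:
        raise ValueError("QM region must be non-empty")
    uniq, counts = np.unique(qm, return_counts=True)
    dup = uniq[counts > 1]
    if dup.size:
        raise ValueError(f"duplicate QM index {int(dup[0])}")
    bad = uniq[(uniq < 0) | (uniq >= total_dof)]
    if bad.size:
        raise ValueError(f"QM index {int(bad[0])} out of range for {total_dof} DOFs")
    mm = np.setdiff1d(np.arange(total_dof), uniq)
    return RegionPartition(qm_indices=np.sort(qm), mm_indices=mm, total_dof=int(total_dof))


@dataclass(frozen=True)
class SubtractiveEnergy:
    """Energy components and combined gradient of one subtractive evaluation."""

    e_full_low: float
    e_qm_low: float
    e_qm_high: float
    e_total: float
    gradient_total: np.ndarray

    @property
    def forces(self) -> np.ndarray:
        return -self.gradient_total


def subtractive_energy_and_gradient(
    partition: RegionPartition,
    high_engine: Engine,
    low_engine: Engine,
    x: np.ndarray,
    state: int = 0,
) -> SubtractiveEnergy:
    """Combine engines subtractively at geometry ``x`` for electronic ``state``.

    The ``state`` index is forwarded to both engines; a low-level engine that is
    electronic-state blind simply ignores it.  Engine failures propagate with
    the offending region and level attached.
    """
    x = np.asarray(x, dtype=float)
    if x.size != partition.total_dof:
        raise ValueError(f"geometry has {x.size} DOFs, partition expects {partition.total_dof}")
    xq = x[partition.qm_indices]

    try:
        e_full_low, g_full_low = low_engine(x, state)
    except Exception as err:  # re-raise with context
        raise RuntimeError(f"low-level engine failed on the full system: {err}") from err
    try:
        e_qm_low, g_qm_low = low_engine(xq, state)
    except Exception as err:
        raise RuntimeError(f"low-level engine failed on the QM region: {err}") from err
    try:
        e_qm_high, g_qm_high = high_engine(xq, state)
    except Exception as err:
        raise RuntimeError(f"high-level engine failed on the QM region (state {state}): {err}") from err

    e_total = e_full_low - e_qm_low + e_qm_high
    grad = np.array(g_full_low, dtype=float, copy=True)
    grad[partition.qm_indices] += np.asarray(g_qm_high, float) - np.asarray(g_qm_low, float)
    return SubtractiveEnergy(
        e_full_low=float(e_full_low),
        e_qm_low=float(e_qm_low),
        e_qm_high=float(e_qm_high),
        e_total=float(e_total),
        gradient_total=grad,
    )
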