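"""Periodic two-dimensional hexagonal lattice geometry.

Cells are addressed in axial coordinates ``(q, r)``; the six neighbors of a
cell are obtained by adding the offsets ``(+1,0), (-1,0), (0,+1), (0,-1),
(+1,-1), (-1,+1)``, with both axes wrapped modulo the lattice dimensions
(a rhombic torus). Every cell therefore has exactly six distinct neighbors
and the neighbor relation is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HEX_OFFSETS", "LatticeConfig", "neighbors", "hex_distance"]

#: Axial-coordinate offsets of the six hexagonal neighbors (dq, dr).
HEX_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (-1, 0),
    (0, 1),
    (0, -1),
    (1, -1),
    (-1, 1),
)

_OFFSETS_ARR = np.array(HEX_OFFSETS, dtype=np.int64)


@dataclass(frozen=True)
class LatticeConfig:
    """Dimensions of the periodic hexagonal lattice.

    Parameters
    ----------
    width, height
        Number of cells along the two axial directions. Both must be >= 3:
        on a dimension-2 torus the +1 and -1 offsets coincide, collapsing
        the six neighbors onto three cells.
    """

    width: int = 100
    height: int = 100

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError(
                f"lattice dimensions must be >= 3, got {self.width}x{self.height}"
            )

    @property
    def capacity(self) -> int:
        return self.width * self.height


def _check_cell(config: LatticeConfig, cell: tuple[int, int]) -> None:
    q, r = cell
    if not (0 <= q < config.width and 0 <= r < config.height):
        raise ValueError(
            f"cell {cell!r} outside lattice [0,{config.width})x[0,{config.height})"
        )


def neighbors(config: LatticeConfig, cell: tuple[int, int]) -> list[tuple[int, int]]:
    """Return the six neighbors of ``cell``, wrapped periodically.

    The order follows :data:`HEX_OFFSETS` and is deterministic.
    """
    _check_cell(config, cell)
    q, r = cell
    return [
        ((q + dq) % config.width, (r + dr) % config.height) for dq, dr in HEX_OFFSETS
    ]


def hex_distance(
    config: LatticeConfig, a: tuple[int, int], b: tuple[int, int]
) -> int:
    """Minimal number of neighbor steps between two cells on the torus.

    For an axial displacement (dq, dr) on an infinite lattice, the hex
    distance is ``(|dq| + |dr| + |dq + dr|) / 2``. On the torus the
    displacement along each axis is only defined modulo the dimension, so the
    minimum is taken over the candidate unwrapped displacements
    ``dq + {-w, 0, +w}`` x ``dr + {-h, 0, +h}``.
    """
    _check_cell(config, a)
    _check_cell(config, b)
    dq = b[0] - a[0]
    dr = b[1] - a[1]
    best = None
    for sq in (-config.width, 0, config.width):
        for sr in (-config.height, 0, config.height):
            uq = dq + sq
            ur = dr + sr
            d = (abs(uq) + abs(ur) + abs(uq + ur)) // 2
            if best is None or d < best:
                best = d
    return int(best)
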