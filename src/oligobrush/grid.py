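"""Discretization of the direction normal to the grafting surface.

The half-space z >= 0 is split into ``n_layers`` slabs of width ``dz``;
all fields and profiles live on the layer centers z_k = (k + 1/2) dz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Uniform 1D layer grid above the wall at z = 0.

    Parameters
    ----------
    n_layers:
        Number of slabs (default 100).
    dz:
        Slab width in nm (default 0.3).
    """

    n_layers: int = 100
    dz: float = 0.3

    def __post_init__(self) -> None:
        if self.n_layers < 3:
            raise ValueError("n_layers must be >= 3")
        if self.dz <= 0:
            raise ValueError("dz must be positive")

    @property
    def centers(self) -> np.ndarray:
        """Layer-center coordinates z_k in nm."""
        return (np.arange(self.n_layers) + 0.5) * self.dz

    @property
    def extent(self) -> float:
        """Total height of the grid in nm."""
        return self.n_layers * self.dz

    def layer_of(self, z: np.ndarray) -> np.ndarray:
        """Half-open binning: layer k covers [k dz, (k+1) dz)."""
        return np.floor(np.asarray(z) / self.dz).astype(np.int64)
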