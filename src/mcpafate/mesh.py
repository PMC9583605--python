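"""Structured 2-D soil-column mesh (x horizontal, y positive downward).

The default vertical discretization mirrors the reference setup: 5 mm cells in
the top metre, 50 mm cells below, and geometric factor-2 refinement of the top
2 cm (1.25 mm cells directly under the infiltration boundary) to resolve steep
initial concentration gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import VanGenuchtenLayer, D_Z_DEFAULT


def _graded_top_widths(dy: float) -> list[float]:
    # factor-2 grading over the top 2 cm: 4 x dy/4, 2 x dy/2, 2 x dy
    return [dy / 4] * 4 + [dy / 2] * 2 + [dy] * 2


@dataclass(frozen=True)
class Mesh:
    """Axis-aligned structured mesh of the simulated soil column."""

    x_edges: np.ndarray  # [m], shape (nx+1,)
    y_edges: np.ndarray  # [m], shape (ny+1,), y=0 at surface, positive down
    layer_index: np.ndarray  # per y-row layer id, shape (ny,)
    d_z: float = D_Z_DEFAULT  # out-of-plane thickness [m]

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges) - 1

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def x_widths(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def y_widths(self) -> np.ndarray:
        return np.diff(self.y_edges)

    @property
    def width(self) -> float:
        return float(self.x_edges[-1] - self.x_edges[0])

    @property
    def depth(self) -> float:
        return float(self.y_edges[-1])

    def cell_volumes(self) -> np.ndarray:
        """Bulk cell volumes [m^3], shape (ny, nx)."""
        return np.outer(self.y_widths, self.x_widths) * self.d_z

    def row_mask(self, y_top: float, y_bottom: float) -> np.ndarray:
        """Boolean mask of rows whose centers lie in [y_top, y_bottom)."""
        yc = self.y_centers
        return (yc >= y_top) & (yc < y_bottom)

    @classmethod
    def build(
        cls,
        layers: list[VanGenuchtenLayer],
        width: float = 0.3,
        dx: float = 5e-3,
        dy: float = 5e-3,
        fine_depth: float = 1.0,
        coarse_dy: float = 50e-3,
        graded_top: bool = True,
        d_z: float = D_Z_DEFAULT,
    ) -> "Mesh":
        """Build a column mesh tiling the depth spanned by ``layers``."""
        depth = max(l.depth_bottom for l in layers)
        widths: list[float] = []
        if graded_top:
            widths.extend(_graded_top_widths(dy))
        y = sum(widths)
        fine_to = min(fine_depth, depth)
        n_fine = int(round((fine_to - y) / dy))
        widths.extend([dy] * n_fine)
        y = sum(widths)
        if depth - y > 1e-12:
            n_coarse = int(round((depth - y) / coarse_dy))
            widths.extend([coarse_dy] * n_coarse)
        y_edges = np.concatenate([[0.0], np.cumsum(widths)])
        if abs(y_edges[-1] - depth) > 1e-9:
            raise ValueError(
                f"mesh does not tile the layer stack: got {y_edges[-1]} m, "
                f"expected {depth} m (adjust dx/dy/coarse_dy)"
            )
        nx = max(1, int(round(width / dx)))
        x_edges = np.linspace(0.0, width, nx + 1)
        yc = 0.5 * (y_edges[:-1] + y_edges[1:])
        layer_index = np.empty(len(yc), dtype=int)
        layer_index.fill(-1)
        for i, layer in enumerate(layers):
            sel = (yc >= layer.depth_top) & (yc < layer.depth_bottom)
            layer_index[sel] = i
        if (layer_index < 0).any():
            raise ValueError("layer stack does not cover every mesh row")
        return cls(x_edges=x_edges, y_edges=y_edges, layer_index=layer_index, d_z=d_z)

    def column_mesh(self) -> "Mesh":
        """Single-column (1-D) version of this mesh with the same y grid."""
        return Mesh(
            x_edges=np.array([self.x_edges[0], self.x_edges[-1]]),
            y_edges=self.y_edges,
            layer_index=self.layer_index,
            d_z=self.d_z,
        )

    def layer_arrays(self, layers: list[VanGenuchtenLayer]) -> dict[str, np.ndarray]:
        """Per-row hydraulic parameter arrays, shape (ny,)."""
        idx = self.layer_index
        def pick(attr):
            return np.array([getattr(layers[i], attr) for i in idx])
        return {
            "theta_s": pick("theta_s"),
            "theta_r": pick("theta_r"),
            "alpha_vg": pick("alpha_vg"),
            "n_vg": pick("n_vg"),
            "l_vg": pick("l_vg"),
            "K_s": pick("K_s"),
            "rho_b": pick("rho_b"),
        }
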