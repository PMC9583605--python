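"""Van Genuchten-Mualem soil hydraulics and variably saturated flow.

The flow problem is one-dimensional in the vertical: hydraulic properties are
uniform within each depth layer and the infiltration forcing is uniform in x,
so the 2-D flow field of every scenario is exactly x-uniform and the solver
operates on a single column (broadcast across columns by the transport stage).

The solver uses a cell-centered finite-volume, mixed-form (theta-h)
formulation with modified-Picard iteration and upstream-weighted inter-cell
conductivities, which keeps the scheme mass conservative through the strongly
nonlinear retention curves of the reference soil.  y is positive downward and
the Darcy flux ``q`` is positive downward: ``q = K(h) (1 - dh/dy)``.
Boundary conditions are a prescribed infiltration flux at the surface and free
drainage (zero pressure-head gradient, q = K) at the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .mesh import Mesh
from .params import VanGenuchtenLayer
from .precip import PrecipSchedule
from .units import SECONDS_PER_DAY, mm_per_day_to_m_per_s


# ---------------------------------------------------------------------------
# van Genuchten - Mualem closed forms
# ---------------------------------------------------------------------------

def _effective_saturation(h, alpha, n):
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / n
    ah = alpha * np.abs(np.minimum(h, 0.0))
    return np.where(h < 0.0, (1.0 + ah ** n) ** (-m), 1.0)


def retention_theta(h, layer: VanGenuchtenLayer):
    """Volumetric water content theta(h) of the van Genuchten retention curve."""
    se = _effective_saturation(h, layer.alpha_vg, layer.n_vg)
    return layer.theta_r + se * (layer.theta_s - layer.theta_r)


def conductivity_K(h, layer: VanGenuchtenLayer):
    """Unsaturated hydraulic conductivity K(h) of the Mualem model."""
    se = _effective_saturation(h, layer.alpha_vg, layer.n_vg)
    return conductivity_from_se(se, layer)


def conductivity_from_se(se, layer: VanGenuchtenLayer):
    m = layer.m_vg
    se = np.clip(np.asarray(se, dtype=float), 0.0, 1.0)
    inner = 1.0 - (1.0 - se ** (1.0 / m)) ** m
    return layer.K_s * se ** layer.l_vg * inner ** 2


def moisture_capacity(h, layer: VanGenuchtenLayer):
    """Specific moisture capacity C(h) = d theta / d h [1/m]."""
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / layer.n_vg
    a, n = layer.alpha_vg, layer.n_vg
    habs = np.abs(np.minimum(h, 0.0))
    ahn = (a * habs) ** n
    cap = (
        (layer.theta_s - layer.theta_r)
        * m * n * a ** n * habs ** (n - 1.0)
        * (1.0 + ahn) ** (-m - 1.0)
    )
    return np.where(h < 0.0, cap, 0.0)


# ---------------------------------------------------------------------------
# flow state containers
# ---------------------------------------------------------------------------

@dataclass
class WaterState:
    """Pressure head, water content and face fluxes of one column snapshot."""

    h: np.ndarray  # pressure head [m], shape (ny,)
    theta: np.ndarray  # volumetric water content [1], shape (ny,)
    q_faces: np.ndarray  # downward Darcy flux [m/s], shape (ny+1,)
    time: float  # [s]


@dataclass
class FlowSeries:
    """Sequence of column snapshots plus cumulative boundary fluxes."""

    times: np.ndarray  # [s]
    h: np.ndarray  # (nt, ny)
    theta: np.ndarray  # (nt, ny)
    q_faces: np.ndarray  # (nt, ny+1)
    inflow: np.ndarray  # cumulative top-boundary influx [m], (nt,)
    outflow: np.ndarray  # cumulative bottom-boundary efflux [m], (nt,)

    def state_at(self, i: int) -> WaterState:
        return WaterState(self.h[i], self.theta[i], self.q_faces[i], self.times[i])


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# column solver
# ---------------------------------------------------------------------------

class RichardsColumn:
    """Mixed-form Richards solver on the vertical grid of ``mesh``."""

    def __init__(
        self,
        mesh: Mesh,
        layers: list[VanGenuchtenLayer],
        tol_h: float = 1e-6,
        max_picard: int = 25,
        cap_floor: float = 1e-9,
    ):
        self.mesh = mesh
        self.layers = layers
        arr = mesh.layer_arrays(layers)
        self.theta_s = arr["theta_s"]
        self.theta_r = arr["theta_r"]
        self.alpha = arr["alpha_vg"]
        self.n = arr["n_vg"]
        self.m = 1.0 - 1.0 / self.n
        self.l = arr["l_vg"]
        self.K_s = arr["K_s"]
        self.rho_b = arr["rho_b"]
        self.dy = mesh.y_widths
        self.yc = mesh.y_centers
        self.dyc = np.diff(self.yc)  # center-to-center distances, (ny-1,)
        self.tol_h = tol_h
        self.max_picard = max_picard
        self.cap_floor = cap_floor

    # vectorized per-row property evaluations --------------------------------
    def theta(self, h: np.ndarray) -> np.ndarray:
        ah = self.alpha * np.abs(np.minimum(h, 0.0))
        se = np.where(h < 0.0, (1.0 + ah ** self.n) ** (-self.m), 1.0)
        return self.theta_r + se * (self.theta_s - self.theta_r)

    def conductivity(self, h: np.ndarray) -> np.ndarray:
        ah = self.alpha * np.abs(np.minimum(h, 0.0))
        se = np.where(h < 0.0, (1.0 + ah ** self.n) ** (-self.m), 1.0)
        inner = 1.0 - (1.0 - np.clip(se, 0.0, 1.0) ** (1.0 / self.m)) ** self.m
        return self.K_s * se ** self.l * inner ** 2

    def capacity(self, h: np.ndarray) -> np.ndarray:
        habs = np.abs(np.minimum(h, 0.0))
        ahn = (self.alpha * habs) ** self.n
        cap = (
            (self.theta_s - self.theta_r)
            * self.m * self.n * self.alpha ** self.n
            * habs ** (self.n - 1.0)
            * (1.0 + ahn) ** (-self.m - 1.0)
        )
        cap = np.where(h < 0.0, cap, 0.0)
        return np.maximum(cap, self.cap_floor)

    def _face_K(self, h: np.ndarray) -> np.ndarray:
        """Upstream-weighted conductivity on interior faces, shape (ny-1,)."""
        K = self.conductivity(h)
        H = h - self.yc  # total head with z = -y
        return np.where(H[:-1] >= H[1:], K[:-1], K[1:])

    def face_fluxes(self, h: np.ndarray, q_top: float) -> np.ndarray:
        """Darcy fluxes on all faces [m/s] for a given head profile."""
        Kf = self._face_K(h)
        q = np.empty(len(h) + 1)
        q[0] = q_top
        q[1:-1] = Kf * (1.0 - np.diff(h) / self.dyc)
        q[-1] = self.conductivity(h[-1:])[0]  # free drainage: unit gradient
        return q

    # time stepping ----------------------------------------------------------
    def _picard_step(self, h_old: np.ndarray, theta_old: np.ndarray,
                     dt: float, q_top: float):
        ny = len(h_old)
        h_m = h_old.copy()
        for it in range(self.max_picard):
            theta_m = self.theta(h_m)
            cap = self.capacity(h_m)
            Kf = self._face_K(h_m)
            K_bot = self.conductivity(h_m[-1:])[0]

            lower = np.zeros(ny)
            diag = cap / dt
            upper = np.zeros(ny)
            rhs = cap * h_m / dt - (theta_m - theta_old) / dt

            # interior faces between rows i and i+1
            g = Kf / self.dyc  # conductance
            # face contributes to divergence of cell i (lower face) and i+1
            diag[:-1] += g / self.dy[:-1]
            upper[:-1] -= g / self.dy[:-1]
            rhs[:-1] -= Kf / self.dy[:-1]
            diag[1:] += g / self.dy[1:]
            lower[1:] -= g / self.dy[1:]
            rhs[1:] += Kf / self.dy[1:]

            # top boundary: prescribed flux into cell 0
            rhs[0] += q_top / self.dy[0]
            # bottom boundary: free drainage out of the last cell
            rhs[-1] -= K_bot / self.dy[-1]

            ab = np.zeros((3, ny))
            ab[0, 1:] = upper[:-1]
            ab[1, :] = diag
            ab[2, :-1] = lower[1:]
            h_new = solve_banded((1, 1), ab, rhs)
            delta = np.max(np.abs(h_new - h_m))
            h_m = h_new
            if delta < self.tol_h:
                return h_m, it + 1
        raise ConvergenceError(f"Picard iteration stalled (delta={delta:.3e} m)")

    def solve(
        self,
        initial: WaterState,
        schedule: PrecipSchedule,
        t_end_days: float,
        output_times_days: np.ndarray | None = None,
        dt_init: float = 600.0,
        dt_max: float = 0.25 * SECONDS_PER_DAY,
        dt_min: float = 1e-3,
    ) -> FlowSeries:
        """Advance the column over ``[t0, t_end]`` under ``schedule``.

        Snapshots are recorded at ``output_times_days`` (default: daily).
        Steps are forced to land on every schedule discontinuity.
        """
        t0_d = initial.time / SECONDS_PER_DAY
        if schedule.t_start > t0_d + 1e-12 or schedule.t_end < t_end_days - 1e-9:
            raise ValueError("schedule does not cover the simulated span")
        if output_times_days is None:
            output_times_days = np.arange(np.ceil(t0_d), t_end_days + 1e-9)
        out_t = np.asarray(output_times_days, dtype=float) * SECONDS_PER_DAY
        breaks = np.unique(np.concatenate([
            schedule.breakpoints() * SECONDS_PER_DAY,
            out_t,
            [initial.time, t_end_days * SECONDS_PER_DAY],
        ]))
        breaks = breaks[(breaks >= initial.time - 1e-6)
                        & (breaks <= t_end_days * SECONDS_PER_DAY + 1e-6)]

        h = initial.h.copy()
        theta = self.theta(h)
        t = initial.time
        inflow = outflow = 0.0
        rec_t, rec_h, rec_th, rec_q, rec_in, rec_out = [], [], [], [], [], []

        def record(time):
            q = self.face_fluxes(h, mm_per_day_to_m_per_s(
                schedule.rate_at(min(time / SECONDS_PER_DAY, schedule.t_end - 1e-9))))
            rec_t.append(time)
            rec_h.append(h.copy())
            rec_th.append(theta.copy())
            rec_q.append(q)
            rec_in.append(inflow)
            rec_out.append(outflow)

        if np.any(np.isclose(out_t, t, atol=1e-6)):
            record(t)
        dt = dt_init
        for seg_start, seg_end in zip(breaks[:-1], breaks[1:]):
            if seg_end - seg_start < 1e-9:
                continue
            q_top = mm_per_day_to_m_per_s(
                schedule.rate_at(seg_start / SECONDS_PER_DAY + 1e-9))
            t = seg_start
            while t < seg_end - 1e-6:
                dt_eff = min(dt, seg_end - t)
                try:
                    h_new, niter = self._picard_step(h, theta, dt_eff, q_top)
                except ConvergenceError:
                    dt *= 0.5
                    if dt < dt_min:
                        raise
                    continue
                q_bot = self.conductivity(h_new[-1:])[0]
                inflow += q_top * dt_eff
                outflow += q_bot * dt_eff
                h = h_new
                theta = self.theta(h)
                t += dt_eff
                if niter <= 6:
                    dt = min(dt * 1.4, dt_max)
                elif niter > 12:
                    dt = max(dt * 0.6, dt_min)
            if np.any(np.isclose(out_t, seg_end, atol=1e-6)):
                record(seg_end)

        return FlowSeries(
            times=np.array(rec_t), h=np.array(rec_h), theta=np.array(rec_th),
            q_faces=np.array(rec_q), inflow=np.array(rec_in),
            outflow=np.array(rec_out),
        )

    def water_balance_error(self, series: FlowSeries) -> float:
        """|Delta storage - (inflow - outflow)| / inflow over the series."""
        storage = series.theta @ self.dy
        dstorage = storage[-1] - storage[0]
        net = (series.inflow[-1] - series.inflow[0]) - (
            series.outflow[-1] - series.outflow[0])
        denom = max(series.inflow[-1] - series.inflow[0], 1e-30)
        return abs(dstorage - net) / denom

    def spin_up(
        self,
        rate_mm_d: float,
        h0: np.ndarray | None = None,
        steady_tol: float = 1e-11,
        max_time_days: float = 20000.0,
    ) -> WaterState:
        """Steady state under constant infiltration ``rate_mm_d``.

        Pseudo-transient continuation: implicit steps with growing dt until
        ``max |dh/dt| < steady_tol`` [m/s].
        """
        if rate_mm_d < 0:
            raise ValueError("infiltration rate must be non-negative")
        q_top = mm_per_day_to_m_per_s(rate_mm_d)
        h = np.full(self.mesh.ny, -1.0) if h0 is None else h0.copy()
        theta = self.theta(h)
        dt = 3600.0
        dt_cap = 200.0 * SECONDS_PER_DAY
        t = 0.0
        while t < max_time_days * SECONDS_PER_DAY:
            try:
                h_new, niter = self._picard_step(h, theta, dt, q_top)
            except ConvergenceError:
                dt *= 0.5
                if dt < 1e-2:
                    raise
                continue
            rate_of_change = np.max(np.abs(h_new - h)) / dt
            t += dt
            h = h_new
            theta = self.theta(h)
            if rate_of_change < steady_tol:
                return WaterState(h, theta, self.face_fluxes(h, q_top), 0.0)
            if niter <= 6:
                dt = min(dt * 2.0, dt_cap)
            elif niter > 12:
                dt = max(dt * 0.5, 1.0)
        raise ConvergenceError("spin-up did not reach steady state")


# ---------------------------------------------------------------------------
# convenience wrappers
# ---------------------------------------------------------------------------

def spin_up(mesh: Mesh, layers, rate_mm_d: float, **kw) -> WaterState:
    return RichardsColumn(mesh.column_mesh(), layers).spin_up(rate_mm_d, **kw)


def solve_flow(mesh: Mesh, layers, schedule: PrecipSchedule,
               initial: WaterState, t_end_days: float, **kw) -> FlowSeries:
    return RichardsColumn(mesh.column_mesh(), layers).solve(
        initial, schedule, t_end_days, **kw)


def steady_constant_flow(mesh: Mesh, layers, rate_mm_d: float) -> WaterState:
    """Spin-up shortcut used as the initial condition of every scenario."""
    return spin_up(mesh, layers, rate_mm_d)
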