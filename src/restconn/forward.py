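"""Five-concentric-sphere volume conductor and lead fields on a source grid.

The head is modeled as five nested spheres (white matter, gray matter, CSF,
skull, skin), each with its own conductivity.  For a current dipole inside
the innermost sphere, the scalp potential is the classical Legendre series:
the infinite-medium dipole expansion provides per-degree source coefficients,
and a per-degree radial boundary-value problem (potential and radial-current
continuity at each interface, zero current through the scalp) yields the
multishell gain for each term.  The series is truncated once terms fall below
a documented tolerance.

The lead field collects, for every voxel of a cubic grid restricted to the
gray-matter sphere, the channels x 3 gain matrix of three orthogonal unit
dipoles.  Columns are average-referenced, matching the referencing of the
data the beamformer sees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from . import config


@dataclass(frozen=True)
class HeadModel:
    """Concentric-sphere conductor; radii in mm (strictly increasing, inside
    out), conductivities in S/m."""

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.conductivities):
            raise ValueError("need one conductivity per shell")
        if any(r2 <= r1 for r1, r2 in zip(self.radii, self.radii[1:])):
            raise ValueError(f"radii must be strictly increasing, got {self.radii}")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    @property
    def inner_radius(self) -> float:
        return self.radii[0]

    @property
    def gray_matter_radius(self) -> float:
        # second shell from the inside for the 5-shell model; innermost otherwise
        return self.radii[1] if len(self.radii) >= 2 else self.radii[0]


def build_head_model(
    radii: tuple[float, ...] = config.HEAD_RADII_MM,
    conductivities: tuple[float, ...] = config.HEAD_CONDUCTIVITIES,
) -> HeadModel:
    """Validated concentric-sphere model; defaults are the package's standard
    5-shell values on an 88 mm scalp sphere."""
    hm = HeadModel(tuple(radii), tuple(conductivities))
    config.log_choice("head_model.radii_mm", hm.radii)
    config.log_choice("head_model.conductivities_S_per_m", hm.conductivities)
    return hm


def _shell_gains(hm: HeadModel, n_max: int) -> np.ndarray:
    """Per-degree gain g[n]: scalp-surface radial factor per unit source
    coefficient c_n (the c_n r^-(n+1) term of the innermost-region source
    potential)."""
    radii = np.asarray(hm.radii, dtype=float)
    sig = np.asarray(hm.conductivities, dtype=float)
    R = radii[-1]
    N = len(radii)
    g = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        if N == 1:
            # closed form: A_1 = (n+1)/n * R^-(2n+1);  g = A_1 R^n + R^-(n+1)
            g[n] = (2 * n + 1) / n * R ** -(n + 1)
            continue
        # unknowns: A_1..A_N, B_2..B_N (B_1 = 1 is the source term)
        nu = 2 * N - 1
        M = np.zeros((nu, nu))
        rhs = np.zeros(nu)
        ai = lambda j: j  # noqa: E731  - column of A_{j+1}
        bi = lambda j: N + j - 1  # noqa: E731  - column of B_{j+1}, j >= 1
        row = 0
        for j in range(N - 1):  # interface between shells j+1 and j+2
            r = radii[j]
            M[row, ai(j)] += r**n
            if j > 0:
                M[row, bi(j)] += r ** -(n + 1)
            M[row, ai(j + 1)] -= r**n
            M[row, bi(j + 1)] -= r ** -(n + 1)
            if j == 0:
                rhs[row] = -(r ** -(n + 1))
            row += 1
            sj, sj1 = sig[j], sig[j + 1]
            M[row, ai(j)] += sj * n * r ** (n - 1)
            if j > 0:
                M[row, bi(j)] += -sj * (n + 1) * r ** -(n + 2)
            M[row, ai(j + 1)] -= sj1 * n * r ** (n - 1)
            M[row, bi(j + 1)] -= -sj1 * (n + 1) * r ** -(n + 2)
            if j == 0:
                rhs[row] = sj * (n + 1) * r ** -(n + 2)
            row += 1
        M[row, ai(N - 1)] = n * R ** (n - 1)
        M[row, bi(N - 1)] = -(n + 1) * R ** -(n + 2)
        sol = np.linalg.solve(M, rhs)
        g[n] = sol[ai(N - 1)] * R**n + sol[bi(N - 1)] * R ** -(n + 1)
    return g


def dipole_potentials(
    hm: HeadModel,
    electrode_pos: np.ndarray,
    dip_pos: np.ndarray,
    dip_mom: np.ndarray,
    n_max: int = 80,
    tol: float = 1e-10,
) -> np.ndarray:
    """Scalp potentials of one dipole (positions mm, moment arbitrary units).

    ``electrode_pos`` is (n_e, 3) on (or near) the scalp sphere.  Potentials
    are returned unreferenced; referencing is the caller's concern.  The
    series is truncated at degree ``n_max`` or once the term ratio
    ``(b/R)**n`` falls below ``tol``.
    """
    electrode_pos = np.atleast_2d(np.asarray(electrode_pos, dtype=float))
    dip_pos = np.asarray(dip_pos, dtype=float)
    dip_mom = np.asarray(dip_mom, dtype=float)
    b = float(np.linalg.norm(dip_pos))
    if b >= hm.inner_radius:
        raise ValueError(
            f"dipole at radius {b:.1f} mm outside the innermost shell "
            f"({hm.inner_radius:.1f} mm)"
        )
    R = hm.scalp_radius
    if b < 1e-9:
        # center: axis degenerate; align it with the moment (only n=1 survives)
        mnorm = np.linalg.norm(dip_mom)
        if mnorm == 0:
            return np.zeros(len(electrode_pos))
        phat = dip_mom / mnorm
    else:
        phat = dip_pos / b
    m_r = float(dip_mom @ phat)
    qt = dip_mom - m_r * phat

    ehat = electrode_pos / np.linalg.norm(electrode_pos, axis=1)[:, None]
    cosg = np.clip(ehat @ phat, -1.0, 1.0)
    eperp = ehat - cosg[:, None] * phat  # magnitude sin(theta), azimuth direction
    tan_proj = eperp @ qt

    g = _shell_gains(hm, n_max)
    sigma1 = hm.conductivities[0]
    x = b / R
    V = np.zeros(len(electrode_pos))
    P_prev = np.ones_like(cosg)  # P_0
    P_cur = cosg.copy()  # P_1
    for n in range(1, n_max + 1):
        bn = b ** (n - 1) if n > 1 else 1.0
        # P_n'(c) from P_n and P_{n-1}; the c = +-1 limit is finite, guard the
        # denominator only
        denom = cosg**2 - 1.0
        safe = np.abs(denom) > 1e-12
        dP = np.zeros_like(cosg)
        dP[safe] = n * (cosg[safe] * P_cur[safe] - P_prev[safe]) / denom[safe]
        dP[~safe] = n * (n + 1) / 2.0 * np.sign(cosg[~safe]) ** (n + 1)
        term = g[n] * bn / (4.0 * np.pi * sigma1) * (n * m_r * P_cur + dP * tan_proj)
        V += term
        if x > 0 and x**n < tol and n > 2:
            break
        # Legendre recurrence
        P_next = ((2 * n + 1) * cosg * P_cur - n * P_prev) / (n + 1)
        P_prev, P_cur = P_cur, P_next
    # mm -> m scaling: positions entered in mm make g ~ mm^-(n+1) consistent
    # with b^n in mm; the 1/(sigma * mm^2) units give V in (moment units)/mm^2
    # per S/m.  With moments in nA*mm this is nV; callers work in arbitrary
    # source units so only relative scale matters.
    return V


@dataclass
class LeadField:
    """Gain matrices on a source grid.

    ``grid`` is (n_vox, 3) voxel centers in mm; ``gains`` is
    (n_vox, n_channels, 3), average-referenced over channels.
    """

    grid: np.ndarray
    gains: np.ndarray
    spacing: float
    channel_labels: list[str]
    electrode_pos: np.ndarray
    head_model: HeadModel

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape[0] != self.grid.shape[0]:
            raise ValueError("one gain matrix per voxel required")
        if not np.isfinite(self.gains).all():
            raise ValueError("lead field contains non-finite gains")

    @property
    def n_voxels(self) -> int:
        return self.grid.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gains.shape[1]

    def nearest_voxel(self, pos) -> int:
        return int(np.argmin(np.linalg.norm(self.grid - np.asarray(pos), axis=1)))


def project_electrodes(hm: HeadModel, positions: np.ndarray, max_off_mm: float = 5.0) -> np.ndarray:
    """Radially project electrode positions onto the scalp sphere.

    Positions further than ``max_off_mm`` from the sphere are rejected: they
    indicate a montage/model mismatch rather than digitization noise.
    """
    positions = np.asarray(positions, dtype=float)
    r = np.linalg.norm(positions, axis=1)
    if (r == 0).any():
        raise ValueError("electrode at head center")
    off = np.abs(r - hm.scalp_radius)
    if (off >= max_off_mm).any():
        worst = int(np.argmax(off))
        raise ValueError(
            f"electrode {worst} is {off[worst]:.1f} mm off the scalp sphere"
        )
    return positions * (hm.scalp_radius / r)[:, None]


def make_source_grid(hm: HeadModel, spacing: float = config.GRID_SPACING_MM) -> np.ndarray:
    """Cubic grid restricted to one voxel inside the gray-matter sphere.

    Beamformer weights diverge at shell boundaries, so the outermost voxel
    layer is excluded.
    """
    r_max = hm.gray_matter_radius - spacing
    axis = np.arange(-r_max, r_max + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.linalg.norm(grid, axis=1) <= r_max + 1e-9
    # exclude the exact center: dipole orientation there is degenerate
    keep &= np.linalg.norm(grid, axis=1) > 1e-9
    return grid[keep]


def compute_lead_field(
    hm: HeadModel,
    electrode_pos: np.ndarray,
    channel_labels: list[str],
    grid_spacing: float = config.GRID_SPACING_MM,
    n_max: int = 80,
) -> LeadField:
    """Average-referenced lead field on a cubic grid.

    Electrodes are projected to the scalp sphere (rejected if off by 5 mm or
    more).  Each voxel's gain matrix holds the potentials of unit dipoles
    along x, y, z.
    """
    epos = project_electrodes(hm, electrode_pos)
    grid = make_source_grid(hm, grid_spacing)
    gains = np.empty((len(grid), len(epos), 3))
    eye = np.eye(3)
    for v, pos in enumerate(grid):
        for k in range(3):
            gains[v, :, k] = dipole_potentials(hm, epos, pos, eye[k], n_max=n_max)
    gains -= gains.mean(axis=1, keepdims=True)  # average reference
    config.log_choice("lead_field.grid_spacing_mm", grid_spacing)
    return LeadField(
        grid=grid,
        gains=gains,
        spacing=grid_spacing,
        channel_labels=list(channel_labels),
        electrode_pos=epos,
        head_model=hm,
    )


def gain_at(lf: LeadField, pos, orientation) -> np.ndarray:
    """Average-referenced channel gains of a dipole at an arbitrary position
    (mm) with a fixed orientation, using the lead field's head model."""
    orientation = np.asarray(orientation, dtype=float)
    n = np.linalg.norm(orientation)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError("orientation must be unit-norm")
    v = dipole_potentials(lf.head_model, lf.electrode_pos, pos, orientation)
    return v - v.mean()
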