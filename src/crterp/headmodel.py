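"""Toy spherical head model and lead field.

A three-shell concentric-sphere conductor (brain, skull, scalp;
conductivities 0.33 / 0.0042 / 0.33 S/m; radii 87 / 92 / 100 mm) with
source nodes on concentric shells inside the brain compartment and
electrodes on the scalp sphere.  The forward solution for a current
dipole is computed per spherical-harmonic degree by solving the radial
boundary-value problem (potential continuity, radial current continuity
at the interfaces, insulating scalp): a 5x5 linear system per degree,
summed over degrees.  For equal conductivities this reduces to the
classical homogeneous-sphere series, which anchors the tests.

Sources are scalar with radial orientation (the position unit vector);
a node at the exact center has no preferred direction and gets zero
gain.  Gain is in microvolts per unit source, one unit = 10 nA*m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, lpmv

from .layout import ElectrodeLayout

__all__ = ["LeadField", "make_toy_leadfield", "dipole_potential"]

#: default shell radii (mm) and conductivities (S/m): brain, skull, scalp
DEFAULT_RADII_MM = (87.0, 92.0, 100.0)
DEFAULT_SIGMAS = (0.33, 0.0042, 0.33)
UNIT_MOMENT_AM = 1e-8  # 10 nA*m


@dataclass
class LeadField:
    """Forward gain from source nodes to electrodes.

    Attributes
    ----------
    gain : (n_nodes, n_channels) ndarray
        uV at each electrode per unit source at each node.
    node_positions : (n_nodes, 3) ndarray, mm
    radii_mm, sigmas : shell geometry the gain was computed with.
    """

    gain: np.ndarray
    node_positions: np.ndarray
    radii_mm: tuple[float, float, float] = DEFAULT_RADII_MM
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite entries")
        if self.gain.shape[0] != self.node_positions.shape[0]:
            raise ValueError("gain rows must match node count")

    @property
    def n_nodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]

    def forward(self, j: np.ndarray) -> np.ndarray:
        """Scalp potentials (channels x time) of node currents (nodes x time)."""
        return self.gain.T @ np.atleast_2d(j)


def _shell_coefficients(
    n_max: int, b: float, radii: tuple[float, float, float],
    sigmas: tuple[float, float, float],
) -> np.ndarray:
    """Surface-potential factor S_n per degree for a unit primary
    r^-(n+1) coefficient from a dipole at radius b (meters)."""
    r1, r2, r3 = radii
    s1, s2, s3 = sigmas
    out = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 ; primary term c * r^-(n+1) in shell 1, c = 1
        m = np.zeros((5, 5))
        rhs = np.zeros(5)
        # V continuity at r1
        m[0] = [r1 ** n, -r1 ** n, -r1 ** -(n + 1), 0, 0]
        rhs[0] = -r1 ** -(n + 1)
        # sigma dV/dr continuity at r1
        m[1] = [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
                s2 * (n + 1) * r1 ** -(n + 2), 0, 0]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # V continuity at r2
        m[2] = [0, r2 ** n, r2 ** -(n + 1), -r2 ** n, -r2 ** -(n + 1)]
        # sigma dV/dr continuity at r2
        m[3] = [0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
                -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)]
        # insulating outer boundary at r3
        m[4] = [0, 0, 0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)]
        sol = np.linalg.solve(m, rhs)
        out[n] = sol[3] * r3 ** n + sol[4] * r3 ** -(n + 1)
    return out


def dipole_potential(
    node_pos_mm: np.ndarray,
    moment: np.ndarray,
    electrode_pos_mm: np.ndarray,
    radii_mm: tuple[float, float, float] = DEFAULT_RADII_MM,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
    n_terms: int = 60,
) -> np.ndarray:
    """Scalp potential (uV) of one dipole at the given electrodes.

    ``moment`` is in units of 10 nA*m; electrode positions must lie on
    the scalp sphere.
    """
    p = np.asarray(node_pos_mm, float) / 1000.0       # m
    q = np.asarray(moment, float) * UNIT_MOMENT_AM    # A*m
    elec = np.asarray(electrode_pos_mm, float) / 1000.0
    radii = tuple(r / 1000.0 for r in radii_mm)
    b = np.linalg.norm(p)
    if b >= radii[0]:
        raise ValueError(f"dipole radius {b * 1000:.1f} mm outside brain shell")
    s1 = sigmas[0]
    if b < 1e-12:
        # dipole at the exact center: axis taken from the moment itself
        qn = np.linalg.norm(q)
        if qn == 0:
            return np.zeros(len(elec))
        zhat = q / qn
        m_r, m_t, that = qn, 0.0, np.zeros(3)
    else:
        zhat = p / b
        m_r = float(q @ zhat)
        t_vec = q - m_r * zhat
        m_t = float(np.linalg.norm(t_vec))
        that = t_vec / m_t if m_t > 0 else np.zeros(3)

    shell = _shell_coefficients(n_terms, b, radii, sigmas)
    n = np.arange(1, n_terms + 1)
    bpow = b ** (n - 1.0)

    r_e = np.linalg.norm(elec, axis=1)
    cosg = np.clip((elec @ zhat) / r_e, -1, 1)
    pn = np.stack([eval_legendre(k, cosg) for k in n])       # n x E
    pn1 = np.stack([lpmv(1, k, cosg) for k in n])
    # azimuth of each electrode around the dipole axis, measured from that
    perp = elec - np.outer(elec @ zhat, zhat)
    pnorm = np.linalg.norm(perp, axis=1)
    cosphi = np.where(pnorm > 0, perp @ that / np.maximum(pnorm, 1e-300), 0.0)

    coef_rad = m_r * n * bpow / (4 * np.pi * s1)
    coef_tan = -m_t * bpow / (4 * np.pi * s1)
    v = (shell[1:, None] * (coef_rad[:, None] * pn
                            + coef_tan[:, None] * pn1 * cosphi[None, :])).sum(axis=0)
    return v * 1e6  # volts -> uV


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n near-uniform unit vectors, randomly rotated."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(1 - z ** 2, 0))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # random rotation for seed-dependent node placement
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    return pts @ q.T


def make_toy_leadfield(
    n_nodes: int = 200,
    layout: ElectrodeLayout | None = None,
    seed: int = 0,
    shell_fractions: tuple[float, ...] = (0.35, 0.55, 0.75, 0.9),
    radii_mm: tuple[float, float, float] = DEFAULT_RADII_MM,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
    n_terms: int = 60,
) -> LeadField:
    """Build a miniature lead field on concentric source shells.

    Nodes are distributed over ``shell_fractions`` of the innermost-shell
    radius (counts proportional to shell area), each with radial
    orientation.  Electrodes come from ``layout`` positions scaled to
    the scalp radius.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if layout is None:
        from .layout import biosemi128_layout

        layout = biosemi128_layout()
    rng = np.random.default_rng(seed)
    r_brain = 0.92 * radii_mm[0]  # stay clearly inside the brain shell
    weights = np.array(shell_fractions, float) ** 2
    counts = np.maximum(np.round(n_nodes * weights / weights.sum()).astype(int), 1)
    while counts.sum() > n_nodes:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_nodes:
        counts[np.argmax(weights)] += 1
    nodes = []
    for frac, cnt in zip(shell_fractions, counts):
        nodes.append(_fibonacci_sphere(cnt, rng) * frac * r_brain)
    node_pos = np.vstack(nodes)

    elec = layout.positions * radii_mm[2]
    gain = np.zeros((len(node_pos), len(elec)))
    for i, p in enumerate(node_pos):
        b = np.linalg.norm(p)
        moment = p / b if b > 0 else np.zeros(3)
        gain[i] = dipole_potential(p, moment, elec, radii_mm, sigmas, n_terms)
    return LeadField(gain, node_pos, radii_mm, sigmas, list(layout.labels))
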