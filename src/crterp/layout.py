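"""Electrode layouts: labeled 3-D sensor positions, ROIs and adjacency.

Positions are stored normalized to the unit sphere.  The packaged
128-channel layout follows the Biosemi ABC naming (A1..D32) with one
alias: site C21, the Fz-equivalent position of that montage, is labeled
``Fz`` so the fronto-central region of interest carries its conventional
10-20 name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "LayoutError",
    "load_layout",
    "biosemi128_layout",
    "FRONTO_CENTRAL_LABELS",
]

#: The 16-channel fronto-central ROI of the Biosemi-128 montage
#: (C21 appears under its 10-20 alias Fz).
FRONTO_CENTRAL_LABELS = (
    "C1", "C2", "C3", "C11", "C12", "C13", "C20", "Fz",
    "C22", "C23", "C24", "C25", "C26", "D1", "D2", "D3",
)


class LayoutError(ValueError):
    """Raised for inconsistent electrode layout definitions."""


@dataclass
class ElectrodeLayout:
    """Labeled unit-sphere electrode positions with ROIs and adjacency.

    Attributes
    ----------
    labels : list of str
        Unique channel labels, in data row order.
    positions : (n_channels, 3) ndarray
        Unit-norm 3-D positions.
    roi_sets : dict
        Named label subsets.
    adjacency : (n, n) bool ndarray or None
        Symmetric, irreflexive neighbor relation; built lazily by
        :func:`crterp.stats.electrode_adjacency` if None.
    """

    labels: list[str]
    positions: np.ndarray
    roi_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    adjacency: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            dupes = {l for l in self.labels if self.labels.count(l) > 1}
            raise LayoutError(f"duplicate electrode labels: {sorted(dupes)}")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise LayoutError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.labels)} labels"
            )
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms <= 0):
            raise LayoutError("zero-length electrode position")
        self.positions = self.positions / norms[:, None]
        for name, roi in self.roi_sets.items():
            missing = [l for l in roi if l not in self.labels]
            if missing:
                raise LayoutError(f"ROI {name!r} references unknown channels {missing}")
        if self.adjacency is not None:
            a = np.asarray(self.adjacency, bool)
            if a.shape != (len(self.labels),) * 2 or not np.array_equal(a, a.T):
                raise LayoutError("adjacency must be a symmetric square boolean matrix")
            np.fill_diagonal(a, False)
            self.adjacency = a

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, labels) -> np.ndarray:
        """Row indices of the given labels (str or iterable of str)."""
        if isinstance(labels, str):
            labels = [labels]
        lut = {l: i for i, l in enumerate(self.labels)}
        try:
            return np.array([lut[l] for l in labels], dtype=int)
        except KeyError as e:
            raise LayoutError(f"unknown channel label {e.args[0]!r}") from None

    def roi_indices(self, name: str) -> np.ndarray:
        if name not in self.roi_sets:
            raise LayoutError(f"unknown ROI {name!r}; have {sorted(self.roi_sets)}")
        return self.index(self.roi_sets[name])


def _attach_standard_rois(layout: ElectrodeLayout) -> None:
    """Attach the fronto-central ROI when all 16 of its labels are present."""
    if all(l in layout.labels for l in FRONTO_CENTRAL_LABELS):
        layout.roi_sets["fronto_central"] = FRONTO_CENTRAL_LABELS


def load_layout(path, require_fronto_central: bool = False) -> ElectrodeLayout:
    """Read electrode coordinates from a whitespace-delimited table.

    One electrode per line: ``label x y z``.  Lines starting with ``#``
    are ignored.  Positions are normalized to the unit sphere; the
    fronto-central ROI is attached if its 16 labels are all present.

    Parameters
    ----------
    require_fronto_central : bool
        If True, raise :class:`LayoutError` naming any missing ROI
        channel instead of silently skipping the ROI.
    """
    labels: list[str] = []
    coords: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise LayoutError(f"{path}:{ln}: expected 'label x y z', got {line!r}")
            labels.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:]])
            except ValueError:
                raise LayoutError(f"{path}:{ln}: non-numeric coordinate in {line!r}")
    layout = ElectrodeLayout(labels=labels, positions=np.array(coords))
    if require_fronto_central:
        missing = [l for l in FRONTO_CENTRAL_LABELS if l not in layout.labels]
        if missing:
            raise LayoutError(f"fronto-central ROI channels missing: {missing}")
    _attach_standard_rois(layout)
    return layout


def biosemi128_layout() -> ElectrodeLayout:
    """The packaged Biosemi-128 layout (C21 aliased to Fz) with the
    fronto-central ROI attached."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi128")
    pos = montage.get_positions()["ch_pos"]
    labels = [("Fz" if l == "C21" else l) for l in pos]
    positions = np.array([pos[l] for l in pos])
    layout = ElectrodeLayout(labels=labels, positions=positions)
    _attach_standard_rois(layout)
    return layout


def save_layout(layout: ElectrodeLayout, path) -> None:
    """Write a layout as a whitespace-delimited ``label x y z`` table."""
    with open(path, "w") as fh:
        fh.write("# label x y z (unit sphere)\n")
        for lab, p in zip(layout.labels, layout.positions):
            fh.write(f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
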