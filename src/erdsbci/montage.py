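"""Electrode grid over frontal/central/parietal cortex and Hjorth neighborhoods.

The 32-channel layout places 10-10 electrodes on a regular grid of six
sagittal rows (F, FC, C, CP, P, PO).  Only the grid topology matters here:
an orthogonal ("Hjorth") Laplacian derivation subtracts from each center
electrode the mean of its up/down/left/right nearest grid neighbors, which
sharpens local cortical activity by removing the common far-field signal.
"""

from __future__ import annotations

# Column convention of the 10-10 system: z -> 0, odd numbers left (negative),
# even numbers right (positive); larger numbers are more lateral.
_COL = {"z": 0, "1": -1, "2": 1, "3": -2, "4": 2, "5": -3, "6": 3}

_ROWS = [
    ("F", ["F5", "F3", "F1", "Fz", "F2", "F4", "F6"]),
    ("FC", ["FC3", "FC1", "FCz", "FC2", "FC4"]),
    ("C", ["C5", "C3", "C1", "Cz", "C2", "C4", "C6"]),
    ("CP", ["CP3", "CP1", "CPz", "CP2", "CP4"]),
    ("P", ["P3", "P1", "Pz", "P2", "P4"]),
    ("PO", ["PO3", "POz", "PO4"]),
]

#: label -> (row, col) grid coordinate
GRID: dict[str, tuple[int, int]] = {}
for _r, (_prefix, _labels) in enumerate(_ROWS):
    for _lab in _labels:
        GRID[_lab] = (_r, _COL[_lab[len(_prefix):]])

#: the default 32-channel montage, row-major (frontal to parieto-occipital)
DEFAULT_LABELS: tuple[str, ...] = tuple(lab for _, labs in _ROWS for lab in labs)

assert len(DEFAULT_LABELS) == 32


def orthogonal_neighbors(label: str, available: list[str] | tuple[str, ...] | None = None) -> list[str]:
    """Up/down/left/right nearest grid neighbors of ``label``.

    Parameters
    ----------
    label
        Electrode name, must be in the default grid.
    available
        If given, restrict neighbors to this set (e.g. a sub-montage).
    """
    if label not in GRID:
        raise KeyError(f"unknown electrode label {label!r}")
    pool = GRID if available is None else {l: GRID[l] for l in available if l in GRID}
    r, c = GRID[label]
    out = []
    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
        for lab, pos in pool.items():
            if pos == (rr, cc) and lab != label:
                out.append(lab)
    return out


def compact_labels(n: int) -> list[str]:
    """The ``n`` grid electrodes closest to Cz (ties: row-major order).

    Useful for reduced problem sizes: the sub-montage is always a connected
    patch over sensorimotor cortex, so Laplacian derivations stay well
    defined.
    """
    if not 1 <= n <= len(DEFAULT_LABELS):
        raise ValueError(f"n must be in [1, {len(DEFAULT_LABELS)}]")
    rz, cz = GRID["Cz"]

    def key(lab: str) -> tuple:
        r, c = GRID[lab]
        return ((r - rz) ** 2 + (c - cz) ** 2, r, c)

    return sorted(DEFAULT_LABELS, key=key)[:n]
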