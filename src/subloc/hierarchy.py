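"""Organelle / suborganelle label layout shared by targets, losses, predictions.

The label space is a grid of up to 8 suborganellar slots under up to 10
organelle columns. Model outputs, binary target matrices and decision rules
all address the same cells, which is what keeps the two prediction levels
consistent: an organelle's score is the maximum over its column, so a
triggered suborganelle always triggers its organelle.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

MAX_ORGANELLES = 10
MAX_SLOTS = 8

#: sentinel accepted by load_hierarchy for the bundled 44-class layout
BUILTIN = "BUILTIN"


class HierarchyError(ValueError):
    pass


@dataclass
class LabelHierarchy:
    organelles: list  # ordered organelle names, length n_organelles <= 10
    grid: list  # MAX_SLOTS lists of length n_organelles; None = EMPTY cell
    name_to_cell: dict  # suborganelle name -> (row, col)

    @property
    def n_organelles(self) -> int:
        return len(self.organelles)

    @property
    def n_cells(self) -> int:
        return MAX_SLOTS * self.n_organelles

    @property
    def occupied(self) -> list:
        """(row, col) of every occupied cell, row-major order."""
        return sorted(self.name_to_cell.values())

    def cell_name(self, row: int, col: int):
        return self.grid[row][col]

    def occupied_mask(self) -> np.ndarray:
        """Binary (8 x n_organelles) matrix marking occupied cells (for the
        mask-out loss mode that excludes EMPTY slots)."""
        m = np.zeros((MAX_SLOTS, self.n_organelles))
        for (r, c) in self.name_to_cell.values():
            m[r, c] = 1.0
        return m

    def organelle_of(self, suborganelle: str) -> str:
        return self.organelles[self.name_to_cell[suborganelle][1]]


def load_hierarchy(spec_path=BUILTIN) -> LabelHierarchy:
    """Load a hierarchy layout from TSV (organelle, suborganelle, slot).

    Organelle order and within-column slot order follow the file. Limits of
    10 organelles and 8 slots per organelle are enforced loudly; duplicate
    suborganelle names are an error.
    """
    if spec_path == BUILTIN:
        text = (
            resources.files("subloc").joinpath("data/hierarchy_default.tsv").read_text()
        )
    else:
        with open(spec_path) as fh:
            text = fh.read()

    organelles: list = []
    entries = []  # (organelle, suborganelle, slot)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise HierarchyError(f"hierarchy spec: expected 3 columns, got {line!r}")
        org, sub, slot = parts[0], parts[1], int(parts[2])
        if org not in organelles:
            organelles.append(org)
        entries.append((org, sub, slot))

    if len(organelles) > MAX_ORGANELLES:
        raise HierarchyError(
            f"{len(organelles)} organelles exceed the {MAX_ORGANELLES}-column layout"
        )
    per_org = {o: 0 for o in organelles}
    for org, _, _ in entries:
        per_org[org] += 1
    for org, n in per_org.items():
        if n > MAX_SLOTS:
            raise HierarchyError(
                f"organelle {org!r} has {n} suborganelles; at most {MAX_SLOTS} fit"
            )

    grid = [[None] * len(organelles) for _ in range(MAX_SLOTS)]
    name_to_cell: dict = {}
    for org, sub, slot in entries:
        if not (0 <= slot < MAX_SLOTS):
            raise HierarchyError(f"slot {slot} for {sub!r} outside 0..{MAX_SLOTS - 1}")
        col = organelles.index(org)
        if sub in name_to_cell:
            raise HierarchyError(f"duplicate suborganelle name {sub!r}")
        if grid[slot][col] is not None:
            raise HierarchyError(
                f"slot {slot} under {org!r} assigned twice "
                f"({grid[slot][col]!r} and {sub!r})"
            )
        grid[slot][col] = sub
        name_to_cell[sub] = (slot, col)
    return LabelHierarchy(organelles=organelles, grid=grid, name_to_cell=name_to_cell)


def labels_to_matrix(record, h: LabelHierarchy):
    """Binary targets for one record: (8 x n_org matrix, n_org vector, lv2 flag).

    Occupied cells named by the record are 1; everything else (including
    EMPTY cells) is 0. The organelle vector is 1 wherever a suborganelle
    label, or a bare organelle label, is annotated. Records with organelle
    labels only are flagged lv2=False and get an all-zero matrix.
    """
    target = np.zeros((MAX_SLOTS, h.n_organelles))
    org_target = np.zeros(h.n_organelles)
    for sub in sorted(record.suborganelle_labels):
        if sub not in h.name_to_cell:
            raise HierarchyError(f"unknown suborganelle label {sub!r}")
        r, c = h.name_to_cell[sub]
        target[r, c] = 1.0
        org_target[c] = 1.0
    for org in sorted(record.organelle_labels):
        if org not in h.organelles:
            raise HierarchyError(f"unknown organelle label {org!r}")
        org_target[h.organelles.index(org)] = 1.0
    lv2 = bool(record.suborganelle_labels)
    return target, org_target, lv2


def matrix_to_labels(matrix: np.ndarray, h: LabelHierarchy) -> set:
    """Suborganelle names of the 1-cells of a binary target matrix."""
    names = set()
    for r in range(MAX_SLOTS):
        for c in range(h.n_organelles):
            if matrix[r, c] >= 0.5 and h.grid[r][c] is not None:
                names.add(h.grid[r][c])
    return names
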