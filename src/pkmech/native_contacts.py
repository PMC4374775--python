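"""Fraction-of-native-contacts (Q) trajectory statistic.

The native contact set of a reference structure is every Calpha pair within
a distance cutoff (default 8 A) and at least ``min_seq_sep`` residues apart
in sequence (default 3), optionally restricted to a domain.  Per trajectory
frame, Q is the fraction of those pairs whose distance has stayed within
``tolerance_factor`` (default 1.2) times its native value.  Q = 1 is the
native state; a drop through ~0.7 marks departure toward the molten
globule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure import DomainDefinition, Structure

__all__ = ["ContactSet", "QSeries", "ca_coordinates", "native_contact_map", "q_trajectory"]


@dataclass
class ContactSet:
    """Native Calpha contacts of a reference selection.

    ``pairs`` holds (i, j, native_distance) with i < j indexing into the
    ordered residue list ``residues`` of (chain, resseq) keys.
    """

    pairs: Tuple[Tuple[int, int, float], ...]
    residues: Tuple[Tuple[str, int], ...]
    cutoff: float
    min_seq_sep: int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class QSeries:
    times: np.ndarray
    q: np.ndarray
    selection: str = "all"

    def frames(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.q.tolist()))


def ca_coordinates(
    s: Structure, selection: DomainDefinition | None = None
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Calpha coordinates and residue keys, ordered by (chain, resseq)."""
    ca = s.atoms[s.atoms["name"] == "CA"].sort_values(["chain", "resseq"])
    if selection is not None:
        ca = ca[selection.mask(ca["resseq"])]
    keys = [(r.chain, int(r.resseq)) for r in ca.itertuples(index=False)]
    return ca[["x", "y", "z"]].to_numpy(dtype=float), keys


def native_contact_map(
    reference: Structure,
    cutoff: float = 8.0,
    min_seq_sep: int = 3,
    selection: DomainDefinition | None = None,
) -> ContactSet:
    """All selected Calpha pairs within ``cutoff`` and >= ``min_seq_sep`` apart.

    Sequence separation is the author residue-number difference within a
    chain; pairs across chains are never native contacts here.  Residues
    without a Calpha are simply absent from the selection (the parser keeps
    whatever atoms exist); a warning is raised if the selection is empty.
    """
    xyz, keys = ca_coordinates(reference, selection)
    name = selection.name if selection is not None else "all"
    if len(keys) == 0:
        warnings.warn(f"selection {name!r} contains no Calpha atoms")
        return ContactSet((), (), cutoff, min_seq_sep)
    pairs = []
    if cutoff > 0 and len(keys) > 1:
        tree = cKDTree(xyz)
        for i, j in sorted(map(tuple, tree.query_pairs(cutoff, output_type="ndarray"))):
            ci, ri = keys[i]
            cj, rj = keys[j]
            if ci != cj or abs(rj - ri) < min_seq_sep:
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            pairs.append((int(i), int(j), d))
    return ContactSet(tuple(pairs), tuple(keys), cutoff, min_seq_sep)


def _frame_coords(
    frame, contacts: ContactSet, selection: DomainDefinition | None
) -> np.ndarray:
    if isinstance(frame, Structure):
        xyz, keys = ca_coordinates(frame, selection)
        if tuple(keys) != contacts.residues:
            raise ValueError(
                "frame residue selection does not match the reference contact set"
            )
        return xyz
    xyz = np.asarray(frame, dtype=float)
    if xyz.shape != (len(contacts.residues), 3):
        raise ValueError(
            f"frame has shape {xyz.shape}, expected ({len(contacts.residues)}, 3)"
        )
    return xyz


def q_trajectory(
    traj: Sequence,
    contacts: ContactSet,
    tolerance_factor: float = 1.2,
    times: Sequence[float] | None = None,
    selection: DomainDefinition | None = None,
) -> QSeries:
    """Per-frame fraction of native contacts retained.

    ``traj`` is a sequence of frames, each either a :class:`Structure`
    (its Calpha atoms, restricted to ``selection``, must match the
    reference selection) or an (n_residues, 3) coordinate array in the
    reference ordering.  A contact is retained when its distance is at most
    ``tolerance_factor`` times the native distance.  An empty contact set
    yields Q = 1 by convention (nothing to lose).
    """
    n = len(contacts)
    qs = []
    for frame in traj:
        xyz = _frame_coords(frame, contacts, selection)
        if n == 0:
            qs.append(1.0)
            continue
        kept = 0
        for i, j, d0 in contacts.pairs:
            if np.linalg.norm(xyz[i] - xyz[j]) <= tolerance_factor * d0:
                kept += 1
        qs.append(kept / n)
    t = (
        np.asarray(list(times), dtype=float)
        if times is not None
        else np.arange(len(qs), dtype=float)
    )
    if len(t) != len(qs):
        raise ValueError("times and trajectory lengths differ")
    sel_name = selection.name if selection is not None else "all"
    return QSeries(times=t, q=np.asarray(qs), selection=sel_name)
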