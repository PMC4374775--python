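"""Seeded generators for every input the analysis pipeline consumes.

The wet inputs of the study - initial-velocity tables, crystal structures,
unfolding trajectories, sequence alignments - are emulated here with known
ground truth, so every downstream stage can be tested end to end without
downloads.  Velocity designs and parameters default to the published
T. pendens conditions (see :mod:`pkmech.designs`); structural fixtures use
idealized geometry (regular aromatic hexagons, 1.39 A bonds).  Every
generator is a bit-reproducible function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import VelocityDataset
from .native_contacts import ContactSet, native_contact_map
from .rate_laws import (
    HillParams,
    InhibitionParams,
    OrderedParams,
    PingPongParams,
    RandomREParams,
    rate_hill,
    rate_inhibited,
    rate_ordered,
    rate_ping_pong,
    rate_random_re,
)
from .structure import ATOM_COLUMNS, Structure

__all__ = [
    "NoiseModel",
    "make_velocity_dataset",
    "make_fixture_structure",
    "make_contact_pair_reference",
    "make_trajectory",
    "make_alignment",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: absolute (fixed sd) or relative (sd = scale*v).

    The default error model of the synthetic studies is 5% relative
    Gaussian noise, matching the visual scatter of replicated initial-rate
    assays.  Velocities are truncated at zero after noising, a slight
    (documented) bias source at very low rates.
    """

    kind: str = "gaussian_relative"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_absolute", "gaussian_relative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def apply(self, v: np.ndarray) -> np.ndarray:
        if self.scale == 0:
            return v.copy()
        rng = np.random.default_rng(self.seed)
        if self.kind == "gaussian_absolute":
            noisy = v + rng.normal(0.0, self.scale, size=v.shape)
        else:
            noisy = v * (1.0 + rng.normal(0.0, self.scale, size=v.shape))
        return np.maximum(noisy, 0.0)


_BISUBSTRATE = {
    "random_re": (rate_random_re, RandomREParams),
    "ordered": (rate_ordered, OrderedParams),
    "ping_pong": (rate_ping_pong, PingPongParams),
}
_INHIBITION = ("competitive", "noncompetitive", "mixed", "uncompetitive")


def make_velocity_dataset(
    model: str,
    params,
    design: Mapping[str, object],
    noise: NoiseModel | None = None,
    replicates: int = 1,
) -> VelocityDataset:
    """Simulate a velocity table from a named rate law on a concentration design.

    ``design`` keys by model family:

    * bisubstrate ("random_re" / "ordered" / "ping_pong"):
      ``a_levels``, ``b_levels`` - the full grid is measured;
    * "hill": ``s_levels``;
    * inhibition kinds: ``s_levels``, ``i_levels`` and optionally
      ``fixed_cosubstrate`` (recorded in the co-substrate column).

    Velocities are the exact model rates plus the noise model, truncated at
    zero; generator settings are recorded in ``design_meta``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if model in _BISUBSTRATE:
        fn, _ = _BISUBSTRATE[model]
        a_levels = np.asarray(design["a_levels"], dtype=float)
        b_levels = np.asarray(design["b_levels"], dtype=float)
        aa, bb = np.meshgrid(a_levels, b_levels, indexing="ij")
        a, b = aa.ravel(), bb.ravel()
        i = np.zeros_like(a)
        v = fn(a, b, params)
        varied = design.get("varied", "a")
    elif model == "hill":
        s = np.asarray(design["s_levels"], dtype=float)
        a, b, i = s, np.zeros_like(s), np.zeros_like(s)
        v = rate_hill(s, params)
        varied = "a"
    elif model in _INHIBITION:
        s_levels = np.asarray(design["s_levels"], dtype=float)
        i_levels = np.asarray(design["i_levels"], dtype=float)
        ss, ii = np.meshgrid(s_levels, i_levels, indexing="ij")
        a, i = ss.ravel(), ii.ravel()
        b = np.full_like(a, float(design.get("fixed_cosubstrate", 0.0)))
        v = rate_inhibited(a, i, params)
        varied = "a"
    else:
        raise ValueError(f"unknown model {model!r}")

    a = np.tile(a, replicates)
    b = np.tile(b, replicates)
    i = np.tile(i, replicates)
    v = np.tile(np.asarray(v, dtype=float), replicates)
    rep = np.repeat(np.arange(replicates), len(a) // replicates)
    if noise is not None:
        v = noise.apply(v)
    meta = (
        f"synthetic model={model} params={params} replicates={replicates} "
        f"noise={noise}"
    )
    return VelocityDataset.from_arrays(a, b, i, v, rep, varied=varied, design_meta=meta)


# ---------------------------------------------------------------------------
# structural fixtures

_RING_RADIUS = 1.39  # regular hexagon, aromatic C-C bond length (A)


def _unit(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def _ring_coords(center, normal) -> Dict[str, np.ndarray]:
    """Ideal planar six-carbon ring centred at ``center``, plane normal ``normal``."""
    center = np.asarray(center, dtype=float)
    n = _unit(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(n, helper))
    w = np.cross(n, u)
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    return {
        name: center
        + _RING_RADIUS * (math.cos(k * math.pi / 3) * u + math.sin(k * math.pi / 3) * w)
        for k, name in enumerate(names)
    }


def make_fixture_structure(
    groups: Sequence[Tuple[str, Mapping[str, object]]],
    chain: str = "A",
    min_separation: float = 1.0,
) -> Structure:
    """Build an idealized test structure from placed interaction groups.

    Supported group kinds and their options:

    * ``phe_ring``: ``center`` (x, y, z), ``normal`` - one PHE aromatic ring
      (ring carbons only);
    * ``lys_glu_pair``: ``distance``, optional ``origin`` - a LYS NZ and a
      GLU OE1 the given distance apart along x (plus CA anchors well away);
    * ``backbone_hbond``: ``distance``, optional ``origin`` - an amide N and
      a carbonyl O of two sequence-distant ALA residues;
    * ``ca_chain``: ``spacing``, ``n``, optional ``origin`` - n GLY Calpha
      atoms collinear along x.

    Residue numbers auto-increment in steps of 10 so neighbour-exclusion
    rules never fire between groups.  Atoms from different groups closer
    than ``min_separation`` (intended partners excepted) are a clash and
    rejected.
    """
    rows: List[tuple] = []
    group_of_atom: List[int] = []
    pair_exempt: set[tuple[int, int]] = set()
    resseq = 0

    def add_atom(gi, res, name, element, pos, this_resseq):
        rows.append(
            (chain, this_resseq, "", res, name, element, float(pos[0]),
             float(pos[1]), float(pos[2]))
        )
        group_of_atom.append(gi)

    for gi, (kind, opts) in enumerate(groups):
        resseq += 10
        origin = np.asarray(opts.get("origin", (0.0, 0.0, 0.0)), dtype=float)
        if kind == "phe_ring":
            ring = _ring_coords(opts["center"], opts.get("normal", (0, 0, 1)))
            for name, pos in ring.items():
                add_atom(gi, "PHE", name, "C", pos, resseq)
        elif kind == "lys_glu_pair":
            d = float(opts["distance"])
            add_atom(gi, "LYS", "CA", "C", origin + (-4.0, 0, 0), resseq)
            add_atom(gi, "LYS", "NZ", "N", origin, resseq)
            resseq += 10
            add_atom(gi, "GLU", "CA", "C", origin + (d + 4.0, 0, 0), resseq)
            add_atom(gi, "GLU", "OE1", "O", origin + (d, 0, 0), resseq)
        elif kind == "backbone_hbond":
            d = float(opts["distance"])
            add_atom(gi, "ALA", "CA", "C", origin + (-1.5, 0, 0), resseq)
            add_atom(gi, "ALA", "N", "N", origin, resseq)
            resseq += 10
            add_atom(gi, "ALA", "O", "O", origin + (d, 0, 0), resseq)
            add_atom(gi, "ALA", "CA", "C", origin + (d + 1.5, 0, 0), resseq)
        elif kind == "ca_chain":
            spacing = float(opts["spacing"])
            n = int(opts["n"])
            for k in range(n):
                resseq += 0 if k == 0 else 1
                add_atom(gi, "GLY", "CA", "C", origin + (k * spacing, 0, 0), resseq)
        else:
            raise ValueError(f"unknown fixture group kind {kind!r}")

    df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    gids = np.asarray(group_of_atom)
    for a in range(len(df)):
        for b in range(a + 1, len(df)):
            if gids[a] == gids[b]:
                continue
            if np.linalg.norm(xyz[a] - xyz[b]) < min_separation:
                raise ValueError(
                    f"clashing placements: atoms {a} and {b} of groups "
                    f"{gids[a]} and {gids[b]} are closer than {min_separation} A"
                )
    return Structure(df, source="synthetic-fixture")


def make_contact_pair_reference(
    n_pairs: int,
    pair_distance: float = 5.0,
    pair_spacing: float = 30.0,
    chain: str = "A",
) -> Structure:
    """Reference whose native contacts are ``n_pairs`` *independent* Ca pairs.

    Pair k is residues (10k+1, 10k+4) - sequence separation 3, spatial
    separation ``pair_distance`` - and distinct pairs sit ``pair_spacing``
    apart, so with the default 8 A cutoff the contact map is exactly one
    contact per pair and no contact shares a residue.  Breaking any subset
    of contacts is then geometrically independent, which is what
    :func:`make_trajectory` needs to realize an exact schedule.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rows = []
    for k in range(n_pairs):
        y = k * pair_spacing
        rows.append((chain, 10 * k + 1, "", "GLY", "CA", "C", 0.0, y, 0.0))
        rows.append((chain, 10 * k + 4, "", "GLY", "CA", "C", pair_distance, y, 0.0))
    return Structure(
        pd.DataFrame(rows, columns=ATOM_COLUMNS), source="synthetic-contact-pairs"
    )


def make_trajectory(
    reference: Structure,
    break_schedule: Mapping[int, float] | Sequence[float],
    seed: int = 0,
    cutoff: float = 8.0,
    min_seq_sep: int = 3,
    tolerance_factor: float = 1.2,
) -> tuple[list[np.ndarray], ContactSet]:
    """Calpha frames realizing a prescribed contact-loss schedule.

    ``break_schedule`` maps frame index -> fraction of native contacts
    broken (or is a plain sequence of fractions).  For each frame, the first
    ``round(fraction * n_contacts)`` contacts in a seeded random order are
    broken by displacing the second residue of the contact radially to
    twice the retention threshold; the order is fixed across frames, so a
    non-decreasing schedule breaks contacts irreversibly.  On a reference
    with independent contacts (see :func:`make_contact_pair_reference`) the
    realized Q equals ``1 - fraction`` to one contact's resolution; with
    shared residues, collateral breakage can overshoot the schedule.

    Returns the frame list (reference Calpha ordering) and the contact set
    used, ready for :func:`pkmech.native_contacts.q_trajectory`.
    """
    if isinstance(break_schedule, Mapping):
        items = sorted(break_schedule.items())
        fractions = [f for _, f in items]
    else:
        fractions = list(break_schedule)
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("schedule fractions must lie in [0, 1]")

    contacts = native_contact_map(reference, cutoff=cutoff, min_seq_sep=min_seq_sep)
    from .native_contacts import ca_coordinates  # local to avoid cycle at import

    xyz0, _ = ca_coordinates(reference)
    n = len(contacts)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    if not fractions:
        return [xyz0.copy()], contacts

    frames = []
    for f in fractions:
        xyz = xyz0.copy()
        k = int(round(f * n))
        for idx in order[:k]:
            i, j, d0 = contacts.pairs[idx]
            direction = xyz[j] - xyz[i]
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            xyz[j] = xyz[i] + direction * (2.0 * tolerance_factor * d0)
        frames.append(xyz)
    return frames, contacts


# ---------------------------------------------------------------------------
# alignments

def _largest_remainder_counts(freqs: Mapping[str, float], n: int) -> Dict[str, int]:
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"column frequencies sum to {total}, not 1")
    items = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    raw = [(res, f * n) for res, f in items]
    counts = {res: int(math.floor(x)) for res, x in raw}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda rx: -(rx[1] - math.floor(rx[1])))
    for res, _ in remainders[:short]:
        counts[res] += 1
    return counts


def make_alignment(
    n_sequences: int,
    column_spec: Mapping[int, Mapping[str, float]],
    length: int | None = None,
    reference_gaps: Sequence[int] = (),
    seed: int = 0,
    reference_id: str = "ref",
    background: str = "A",
) -> List[Tuple[str, str]]:
    """Alignment with prescribed residue frequencies at reference positions.

    ``column_spec`` maps a 1-based *reference* position to a residue
    frequency table; frequencies are realized exactly (largest-remainder
    allocation over the ``n_sequences`` rows, reference included), so a
    70/30 split over 10 sequences yields literally 7 and 3.  One seeded
    permutation of the rows is shared by all specified columns: sequences
    are comonotone across columns, so jointly planted motifs (for
    covariation tests) line up by construction.

    ``reference_gaps`` lists 0-based alignment columns where the reference
    carries a gap (these columns are background residues in the other rows
    and shift the position-to-column mapping as in real alignments).
    Everything unspecified is the ``background`` residue.  The first record
    is the reference.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    ref_positions = sorted(column_spec)
    gap_cols = sorted(set(reference_gaps))
    ref_len_needed = max(ref_positions) if ref_positions else 1
    ungapped_len = max(ref_len_needed, length or 0)
    total_len = ungapped_len + len(gap_cols)
    if any(not 0 <= g < total_len for g in gap_cols):
        raise ValueError("reference gap columns out of range")

    # column index of each reference position, skipping reference gaps
    non_gap_cols = [c for c in range(total_len) if c not in set(gap_cols)]
    col_of = {p: non_gap_cols[p - 1] for p in ref_positions}

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_sequences)

    grid = np.full((n_sequences, total_len), background, dtype="<U1")
    for g in gap_cols:
        grid[0, g] = "-"
    for p in ref_positions:
        counts = _largest_remainder_counts(column_spec[p], n_sequences)
        col = col_of[p]
        fill = []
        for res, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            fill.extend([res] * c)
        for rank, res in enumerate(fill):
            grid[perm[rank], col] = res
    # reference row: keep its gap columns even if a spec column collides
    for g in gap_cols:
        grid[0, g] = "-"

    out = []
    for k in range(n_sequences):
        rid = reference_id if k == 0 else f"seq{k}"
        out.append((rid, "".join(grid[k])))
    return out


def alignment_to_fasta(records: Iterable[Tuple[str, str]]) -> str:
    return "".join(f">{rid}\n{seq}\n" for rid, seq in records)
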