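"""Salt-bridge contact statistics between fibril basic residues and HCGs.

A side chain and a charged group are in contact when a cationic nitrogen
(Lys NZ, Arg NH1/NH2) lies within 4.5 Å (inclusive) of one of the group's
anionic oxygens (sulfate, sulfamido, or carboxylate).  Contacts are
recorded at residue x layer x HCG granularity, so each rung of an axial
residue ladder counts separately; per-frame statistics reduce these to
unique-residue and unique-HCG bound counts, medians over frames, and
unit/group-resolved contact-frequency maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Pose
from .model_builder import GROUP_TYPES


@dataclass
class ContactParams:
    cutoff: float = 4.5    # Å, inclusive

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ContactSeries:
    """Per-frame contact sets; each contact is (residue, layer, hcg_id)."""

    frames: list = field(default_factory=list)

    def append(self, contacts: set) -> None:
        self.frames.append(set(contacts))

    def __len__(self) -> int:
        return len(self.frames)


def detect_contacts(pose: Pose, fibril, glycan,
                    params: ContactParams | None = None) -> set:
    """All salt-bridge contacts for one frame.

    Returns a set of ``(residue_number, layer_index, hcg_id)`` tuples.
    """
    params = params or ContactParams()
    cat_pos, cat_res, cat_layer, _ = fibril.cationic_atoms()
    if len(cat_pos) == 0:
        return set()
    ox_body, ox_ids = glycan.hcg_oxygens()
    if len(ox_body) == 0:
        return set()
    ox = pose.apply(ox_body)
    tree = cKDTree(cat_pos)
    contacts = set()
    for neigh, hid in zip(tree.query_ball_point(ox, params.cutoff), ox_ids):
        for a in neigh:
            contacts.add((int(cat_res[a]), int(cat_layer[a]), int(hid)))
    return contacts


def frame_counts(contacts: set) -> tuple[int, int]:
    """(unique residues bound, unique HCGs bound) for one frame.

    Residues are counted at residue x layer granularity (each ladder rung
    separately); an HCG counts once no matter how many residues it touches.
    """
    residues = {(r, l) for r, l, _ in contacts}
    hcgs = {h for _, _, h in contacts}
    return len(residues), len(hcgs)


def _lower_median(values) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def median_bound(series: ContactSeries, which: str = "residues",
                 site_filter=None):
    """Median per-frame bound count and its full distribution.

    ``which`` selects unique residues or unique HCGs; ``site_filter``
    restricts contacts to the given residue numbers first.  The median uses
    the lower-median convention for even-length samples, so integer counts
    yield integer medians.  Returns ``(median, histogram dict)``.
    """
    if len(series) == 0:
        raise ValueError("contact series has no frames")
    if which not in ("residues", "hcgs"):
        raise ValueError("which must be 'residues' or 'hcgs'")
    counts = []
    for frame in series.frames:
        if site_filter is not None:
            frame = {c for c in frame if c[0] in site_filter}
        nr, nh = frame_counts(frame)
        counts.append(nr if which == "residues" else nh)
    hist = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    total = len(counts)
    distribution = {c: hist[c] / total for c in sorted(hist)}
    return _lower_median(counts), distribution


def frequency_map(series: ContactSeries, glycan, fibril,
                  params: ContactParams | None = None,
                  include_sulfamido: bool = True) -> pd.DataFrame:
    """Ensemble-averaged contact frequencies by glycan unit/group x residue.

    Each cell is the fraction of frames in which the given (unit, group
    type) HCG touches the given residue in at least one fibril layer
    (contacts are pooled over layers, so cells stay in [0, 1]).  Sulfamido
    groups occupy their own column block by default; ``include_sulfamido=
    False`` drops them for sulfate/carboxylate-only figure parity.
    """
    if len(series) == 0:
        raise ValueError("contact series has no frames")
    groups = GROUP_TYPES if include_sulfamido else tuple(
        g for g in GROUP_TYPES if g != "N_sulfamido")
    hcg_key = {h.hcg_id: (h.unit_index, h.group_type) for h in glycan.hcgs
               if h.group_type in groups}
    residues = sorted(set(int(r) for r in np.unique(fibril.res_numbers[
        (fibril.res_names == "LYS") | (fibril.res_names == "ARG")])))
    rows = sorted(set(hcg_key.values()))
    mat = np.zeros((len(rows), len(residues)))
    row_idx = {rg: i for i, rg in enumerate(rows)}
    col_idx = {r: j for j, r in enumerate(residues)}
    for frame in series.frames:
        seen = set()
        for res, _layer, hid in frame:
            if hid in hcg_key and res in col_idx:
                seen.add((hcg_key[hid], res))
        for rg, res in seen:
            mat[row_idx[rg], col_idx[res]] += 1
    mat /= len(series)
    index = pd.MultiIndex.from_tuples(rows, names=["unit", "group"])
    return pd.DataFrame(mat, index=index, columns=residues)


def contacts_from_outcomes(outcomes, fibril, glycan,
                           params: ContactParams | None = None,
                           site_filter=None) -> ContactSeries:
    """Build a contact series from reacted BD final poses (one frame each)."""
    series = ContactSeries()
    for out in outcomes:
        if out.status != "reacted":
            continue
        if site_filter is not None and out.site not in site_filter:
            continue
        series.append(detect_contacts(out.final_pose, fibril, glycan, params))
    return series
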