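"""Synthetic fibril and glycan structure generators, plus PDB round-trip I/O.

The fibril generator produces an idealized parallel in-register cross-beta
stack: a single 2D cross-section template (one residue per sequence letter,
charged side-chain atoms at fixed offsets) replicated every ``rise`` Å along
the z axis, so that identical residues form axial "ladders".  Basic ladders
(Lys/Arg) are the candidate polyanion binding sites.

The glycan generator produces an extended heparin-like chain of alternating
glucosamine / iduronic-acid units.  Each unit carries its sulfur reference
atoms and its anionic charged groups (HCGs): N-sulfamido and 6-O-sulfate on
glucosamine, 2-O-sulfate and the ring carboxylate on iduronic acid.  A fully
sulfated chain of n saccharides therefore carries exactly 2n HCGs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .geometry import Pose

AA_3LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA_1LETTER = {v: k for k, v in AA_3LETTER.items()}

CHARGE_RULES = {"K": 1, "R": 1, "D": -1, "E": -1}

#: tau fibril core sequence, residues 306-378 (the region forming the
#: cross-beta core of both disease-derived polymorphs)
TAU_CORE_SEQUENCE = (
    "VQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITHVPGGGNKKIETHKLTF"
)
TAU_CORE_START = 306
#: basic residues whose side chains face the fibril interior in the core fold
TAU_BURIED_BASIC = frozenset({370})

GROUP_TYPES = ("N_sulfamido", "O6X", "OS2X", "OS6X")


# ---------------------------------------------------------------------------
# cross-section template
# ---------------------------------------------------------------------------

@dataclass
class TemplateResidue:
    number: int
    name: str                       # 3-letter code
    backbone_xy: np.ndarray         # (2,) CA position in the cross-section
    sidechain_offsets: dict         # atom name -> (3,) offset from CA
    charge: int                     # formal charge carried by the side chain
    solvent_exposed: bool = True

    @property
    def letter(self) -> str:
        return AA_1LETTER[self.name]


@dataclass
class CrossSectionTemplate:
    residues: list

    def __post_init__(self):
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("residue numbers must be strictly increasing")

    @property
    def site_list(self) -> list:
        """Residue numbers eligible as binding sites: basic and exposed."""
        return [r.number for r in self.residues
                if r.charge == +1 and r.solvent_exposed]

    def __len__(self) -> int:
        return len(self.residues)


def _sidechain_atoms(letter: str, outward: np.ndarray) -> tuple[dict, int]:
    """Side-chain atom offsets (3D, from CA) and formal charge for one residue.

    ``outward`` is the in-plane unit vector pointing away from the fibril
    cross-section, so charged groups sit on the solvent face.
    """
    out = np.array([outward[0], outward[1], 0.0])
    perp = np.array([-outward[1], outward[0], 0.0])
    charge = CHARGE_RULES.get(letter, 0)
    if letter == "K":
        return {"NZ": 5.0 * out}, charge
    if letter == "R":
        return {
            "CZ": 5.5 * out,
            "NH1": 5.5 * out + 1.1 * perp + np.array([0, 0, 0.4]),
            "NH2": 5.5 * out - 1.1 * perp + np.array([0, 0, 0.4]),
        }, charge
    if letter == "D":
        return {"OD1": 3.2 * out}, charge
    if letter == "E":
        return {"OE1": 4.2 * out}, charge
    return {}, charge


def build_cross_section(sequence: str, start_number: int = 1,
                        layout: str = "ladder_line", spacing: float = 3.5,
                        c_radius: float | None = None,
                        buried: frozenset | set = frozenset()) -> CrossSectionTemplate:
    """Build a single-layer cross-section from a one-letter sequence.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence of the cross-section.
    start_number : int
        Residue number of the first residue.
    layout : {"ladder_line", "C_shape"}
        ``ladder_line`` places CA atoms on a straight line with every side
        chain pointing to +y, so all ladders are maximally exposed.
        ``C_shape`` places CA atoms on a circular arc with side chains
        pointing radially outward, mimicking the C-shaped amyloid fold.
    spacing : float
        CA-CA distance along the backbone trace, Å.
    buried : set of int
        Residue numbers whose side chains are declared solvent-inaccessible.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if layout not in ("ladder_line", "C_shape"):
        raise ValueError(f"unknown layout {layout!r}")
    residues = []
    n = len(sequence)
    for i, letter in enumerate(sequence.upper()):
        if letter not in AA_3LETTER:
            raise ValueError(f"unknown residue letter {letter!r} at position {i}")
        if layout == "ladder_line":
            xy = np.array([i * spacing, 0.0])
            outward = np.array([0.0, 1.0])
        else:
            radius = c_radius if c_radius is not None else spacing * n / (1.5 * np.pi)
            # arc spanning 270 degrees, side chains radially outward
            theta = 1.5 * np.pi * i / max(n - 1, 1)
            xy = radius * np.array([np.cos(theta), np.sin(theta)])
            outward = np.array([np.cos(theta), np.sin(theta)])
        offsets, charge = _sidechain_atoms(letter, outward)
        number = start_number + i
        residues.append(TemplateResidue(
            number=number,
            name=AA_3LETTER[letter],
            backbone_xy=xy,
            sidechain_offsets=offsets,
            charge=charge,
            solvent_exposed=number not in buried,
        ))
    return CrossSectionTemplate(residues)


def tau_core_template(layout: str = "C_shape") -> CrossSectionTemplate:
    """Packaged tau-like fixture: the 73-residue fibril core (306-378).

    The solvent-exposed basic residues reproduce the canonical binding-site
    list K311, K317, K321, K331, K340, K343, K347, R349, K353, K369, K375.
    """
    return build_cross_section(
        TAU_CORE_SEQUENCE, start_number=TAU_CORE_START, layout=layout,
        buried=TAU_BURIED_BASIC,
    )


# ---------------------------------------------------------------------------
# fibril
# ---------------------------------------------------------------------------

@dataclass
class FibrilModel:
    """Stacked-layer fibril: flat atom arrays plus geometry metadata."""

    positions: np.ndarray           # (N, 3) Å
    charges: np.ndarray             # (N,) e
    res_numbers: np.ndarray         # (N,) int
    res_names: np.ndarray           # (N,) 3-letter str
    layer_index: np.ndarray         # (N,) 0-based int
    atom_names: np.ndarray          # (N,) str
    roles: np.ndarray               # (N,) str
    n_layers: int
    rise: float
    n_protofilaments: int = 1
    protofilament_transform: Pose | None = None
    site_list: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def bounding_radius(self) -> float:
        return float(np.linalg.norm(self.positions - self.centroid, axis=1).max())

    def layer_centroids(self) -> np.ndarray:
        """(n_layers, 3) centroid of each layer, pooled over protofilaments."""
        cents = np.empty((self.n_layers, 3))
        for k in range(self.n_layers):
            cents[k] = self.positions[self.layer_index == k].mean(axis=0)
        return cents

    # -- charge / reference selections -------------------------------------

    @property
    def charge_mask(self) -> np.ndarray:
        return self.charges != 0

    @property
    def charge_positions(self) -> np.ndarray:
        return self.positions[self.charge_mask]

    @property
    def charge_values(self) -> np.ndarray:
        return self.charges[self.charge_mask]

    def bd_reference_atoms(self):
        """BD reaction reference atoms: NZ of exposed Lys, CZ of exposed Arg.

        Returns (positions (M,3), residue numbers (M,), layer indices (M,)).
        """
        site = np.isin(self.res_numbers, self.site_list)
        mask = site & (
            ((self.res_names == "LYS") & (self.atom_names == "NZ"))
            | ((self.res_names == "ARG") & (self.atom_names == "CZ"))
        )
        return self.positions[mask], self.res_numbers[mask], self.layer_index[mask]

    def cationic_atoms(self):
        """Salt-bridge donors: NZ of Lys, NH1/NH2 of Arg (all layers).

        Returns (positions, residue numbers, layer indices, atom names).
        """
        mask = (
            ((self.res_names == "LYS") & (self.atom_names == "NZ"))
            | ((self.res_names == "ARG")
               & np.isin(self.atom_names, ["NH1", "NH2"]))
        )
        return (self.positions[mask], self.res_numbers[mask],
                self.layer_index[mask], self.atom_names[mask])

    def residue_atom_mask(self, residue_numbers) -> np.ndarray:
        return np.isin(self.res_numbers, list(residue_numbers))


def build_fibril(template: CrossSectionTemplate, n_layers: int,
                 rise: float = 4.8, twist_deg: float = 0.0,
                 n_protofilaments: int = 1,
                 protofilament_transform: Pose | None = None) -> FibrilModel:
    """Stack ``n_layers`` congruent copies of the cross-section along z.

    Layer k is the template rotated by ``k * twist_deg`` about z (default no
    twist) and translated by ``k * rise``.  An optional second protofilament
    is a rigid copy of the first.
    """
    if n_layers < 3:
        raise ValueError("n_layers must be >= 3 (axis definition needs "
                         "distinct interior layers)")
    if rise <= 0:
        raise ValueError("rise must be positive")
    if n_protofilaments not in (1, 2):
        raise ValueError("n_protofilaments must be 1 or 2")
    if n_protofilaments == 2 and protofilament_transform is None:
        # default: C2 copy rotated 180 deg about z, offset in x
        width = max(np.linalg.norm(r.backbone_xy) for r in template.residues)
        rot = np.diag([-1.0, -1.0, 1.0])
        protofilament_transform = Pose(rot, np.array([2.4 * width + 12.0, 0.0, 0.0]))

    pos, chg, rnum, rname, lay, anames, roles = [], [], [], [], [], [], []

    def emit(residue, position, charge, layer, atom_name, role):
        pos.append(position)
        chg.append(charge)
        rnum.append(residue.number)
        rname.append(residue.name)
        lay.append(layer)
        anames.append(atom_name)
        roles.append(role)

    for k in range(n_layers):
        ang = np.deg2rad(twist_deg) * k
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([0.0, 0.0, k * rise])
        for res in template.residues:
            ca = np.array([res.backbone_xy[0], res.backbone_xy[1], 0.0])
            emit(res, rot @ ca + shift, 0.0, k, "CA", "backbone")
            for name, off in res.sidechain_offsets.items():
                p = rot @ (ca + np.asarray(off, dtype=float)) + shift
                if name in ("NZ", "CZ", "OD1", "OE1"):
                    role = "charged_sidechain"
                    charge = float(res.charge)
                else:
                    role = "contact_reference"
                    charge = 0.0
                emit(res, p, charge, k, name, role)

    positions = np.array(pos)
    charges = np.array(chg)
    res_numbers = np.array(rnum)
    res_names = np.array(rname)
    layer_index = np.array(lay)
    atom_names = np.array(anames)
    role_arr = np.array(roles)

    if n_protofilaments == 2:
        p2 = protofilament_transform.apply(positions)
        positions = np.vstack([positions, p2])
        charges = np.concatenate([charges, charges])
        res_numbers = np.concatenate([res_numbers, res_numbers])
        res_names = np.concatenate([res_names, res_names])
        layer_index = np.concatenate([layer_index, layer_index])
        atom_names = np.concatenate([atom_names, atom_names])
        role_arr = np.concatenate([role_arr, role_arr])

    return FibrilModel(
        positions=positions, charges=charges, res_numbers=res_numbers,
        res_names=res_names, layer_index=layer_index, atom_names=atom_names,
        roles=role_arr, n_layers=n_layers, rise=rise,
        n_protofilaments=n_protofilaments,
        protofilament_transform=protofilament_transform,
        site_list=list(template.site_list),
    )


# ---------------------------------------------------------------------------
# glycan
# ---------------------------------------------------------------------------

@dataclass
class HCG:
    """One heparin charged group: an anionic oxygen-bearing substituent."""

    hcg_id: int
    unit_index: int                 # 1-based saccharide index
    group_type: str                 # one of GROUP_TYPES
    oxygen_positions: np.ndarray    # (k, 3) body frame Å
    charge: float = -1.0

    @property
    def charge_position(self) -> np.ndarray:
        return self.oxygen_positions.mean(axis=0)


@dataclass
class GlycanUnit:
    unit_index: int
    unit_kind: str                  # "glucosamine" | "iduronic_acid"
    ring_centroid: np.ndarray       # (3,)
    sulfurs: dict                   # name ("S2"/"S6") -> (3,) position


@dataclass
class GlycanModel:
    """Linear heparin-like chain in its body frame (centroid near origin)."""

    units: list
    hcgs: list
    sulfation_pattern: str

    @property
    def n_saccharides(self) -> int:
        return len(self.units)

    @property
    def net_charge(self) -> float:
        return float(sum(h.charge for h in self.hcgs))

    @property
    def ring_centroids(self) -> np.ndarray:
        return np.array([u.ring_centroid for u in self.units])

    def sulfur_atoms(self):
        """Ordered sulfur reference atoms (unit order, S2 before S6).

        Returns (positions (S,3), labels list of (unit_index, name)).
        """
        positions, labels = [], []
        for u in self.units:
            for name in sorted(u.sulfurs):
                positions.append(u.sulfurs[name])
                labels.append((u.unit_index, name))
        return np.array(positions).reshape(-1, 3), labels

    @property
    def sulfur_positions(self) -> np.ndarray:
        return self.sulfur_atoms()[0]

    @property
    def charge_positions(self) -> np.ndarray:
        return np.array([h.charge_position for h in self.hcgs])

    @property
    def charge_values(self) -> np.ndarray:
        return np.array([h.charge for h in self.hcgs])

    def hcg_oxygens(self):
        """All HCG oxygens flattened: (positions (K,3), hcg ids (K,))."""
        positions, ids = [], []
        for h in self.hcgs:
            for o in h.oxygen_positions:
                positions.append(o)
                ids.append(h.hcg_id)
        return np.array(positions), np.array(ids)


#: idealized sulfate: three terminal oxygens around the sulfur
_SULFATE_O = np.array([
    [1.45, 0.0, 0.0],
    [-0.72, 1.25, 0.0],
    [-0.72, -1.25, 0.0],
])


def build_glycan(n_saccharides: int, sulfation_pattern: str = "full",
                 repeat_rise: float = 8.7) -> GlycanModel:
    """Build an extended heparin-like chain.

    Units alternate glucosamine (odd 1-based index) and iduronic acid (even).
    Under full sulfation each glucosamine carries an N-sulfamido group (S2
    sulfur) and a 6-O-sulfate (S6); each iduronic acid carries a 2-O-sulfate
    (S2) and its ring carboxylate, for 2 HCGs per saccharide.  The
    ``desulfated_2O`` variant removes all 2-O-sulfates, ``desulfated_6O``
    all 6-O-sulfates.

    ``repeat_rise`` is the disaccharide repeat length in Å (helical heparin
    repeat ~8.7 Å), so units are spaced ``repeat_rise / 2`` apart.
    """
    if n_saccharides < 2 or n_saccharides % 2 != 0:
        raise ValueError("n_saccharides must be even and >= 2")
    if repeat_rise <= 0:
        raise ValueError("repeat_rise must be positive")
    if sulfation_pattern not in ("full", "desulfated_2O", "desulfated_6O"):
        raise ValueError(f"unknown sulfation pattern {sulfation_pattern!r}")

    spacing = repeat_rise / 2.0
    # center the chain on the origin so the body frame centroid is ~0
    x0 = -(n_saccharides - 1) * spacing / 2.0

    units, hcg_specs = [], []
    for i in range(1, n_saccharides + 1):
        centroid = np.array([x0 + (i - 1) * spacing, 0.0, 0.0])
        flip = 1.0 if i % 2 == 1 else -1.0   # alternate substituent faces
        if i % 2 == 1:
            kind = "glucosamine"
            sulfurs = {}
            # N-sulfamido sulfur (always present on GlcNS)
            s2 = centroid + np.array([0.0, 2.2 * flip, 0.8])
            sulfurs["S2"] = s2
            hcg_specs.append((i, "N_sulfamido", s2 + _SULFATE_O))
            if sulfation_pattern != "desulfated_6O":
                s6 = centroid + np.array([0.9, -2.2 * flip, -0.6])
                sulfurs["S6"] = s6
                hcg_specs.append((i, "OS6X", s6 + _SULFATE_O))
        else:
            kind = "iduronic_acid"
            sulfurs = {}
            if sulfation_pattern != "desulfated_2O":
                s2 = centroid + np.array([0.0, 2.2 * flip, -0.8])
                sulfurs["S2"] = s2
                hcg_specs.append((i, "OS2X", s2 + _SULFATE_O))
            carbox = centroid + np.array([-0.5, -2.0 * flip, 0.0])
            ox = np.array([carbox + [0.0, -0.6 * flip, 0.7],
                           carbox + [0.0, -0.6 * flip, -0.7]])
            hcg_specs.append((i, "O6X", ox))
        units.append(GlycanUnit(i, kind, centroid, sulfurs))

    hcg_specs.sort(key=lambda t: (t[0], t[1]))
    hcgs = [HCG(hcg_id=j, unit_index=u, group_type=g,
                oxygen_positions=np.atleast_2d(np.asarray(o, dtype=float)))
            for j, (u, g, o) in enumerate(hcg_specs)]
    return GlycanModel(units=units, hcgs=hcgs,
                       sulfation_pattern=sulfation_pattern)


def enumerate_hcgs(glycan: GlycanModel) -> list:
    """Charged groups in deterministic (unit_index, group_type) order."""
    return sorted(glycan.hcgs, key=lambda h: (h.unit_index, h.group_type))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _validate_pdb_lines(path) -> None:
    with open(path) as fh:
        n_atoms = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_atoms += 1
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    raise ValueError(
                        f"malformed ATOM record at line {lineno} of {path}")
    if n_atoms == 0:
        raise ValueError(f"no ATOM/HETATM records in {path}")


def write_pdb(model: FibrilModel, path) -> None:
    """Write the fibril as a standard PDB file, one chain per layer."""
    n = len(model)
    arr = struc.AtomArray(n)
    arr.coord = model.positions.astype(np.float32)
    arr.chain_id = np.array(
        [_CHAIN_IDS[k % len(_CHAIN_IDS)] for k in model.layer_index])
    arr.res_id = model.res_numbers
    arr.res_name = model.res_names
    arr.atom_name = model.atom_names
    arr.element = np.array([name[0] for name in model.atom_names])
    arr.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def read_pdb(path, rise_hint: float = 4.8) -> FibrilModel:
    """Read a fibril from PDB, assigning layers by chain or axial binning.

    Charges and reference roles are re-derived from residue/atom names using
    the same formal-charge rules as the generator.  If the file has more
    than one chain, each chain is one layer; otherwise atoms are binned along
    the principal axis with ``rise_hint`` spacing.
    """
    _validate_pdb_lines(path)
    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    if arr.array_length() == 0:
        raise ValueError(f"no atoms parsed from {path}")

    chains = np.unique(arr.chain_id)
    if len(chains) > 1:
        order = {c: i for i, c in enumerate(chains)}
        layer = np.array([order[c] for c in arr.chain_id])
    else:
        coords = arr.coord.astype(float)
        centered = coords - coords.mean(axis=0)
        # principal axis via SVD; project and bin at the rise spacing
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        layer = np.round((proj - proj.min()) / rise_hint).astype(int)
        layer -= layer.min()

    res_names = np.array(arr.res_name)
    atom_names = np.array(arr.atom_name)
    charges = np.zeros(arr.array_length())
    roles = np.full(arr.array_length(), "backbone", dtype=object)
    for rn, an, q in (("LYS", "NZ", 1.0), ("ARG", "CZ", 1.0),
                      ("ASP", "OD1", -1.0), ("GLU", "OE1", -1.0)):
        m = (res_names == rn) & (atom_names == an)
        charges[m] = q
        roles[m] = "charged_sidechain"
    roles[(res_names == "ARG") & np.isin(atom_names, ["NH1", "NH2"])] = \
        "contact_reference"

    n_layers = int(layer.max()) + 1
    cents = np.array([arr.coord[layer == k].mean(axis=0)
                      for k in range(n_layers)])
    spacings = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    rise = float(spacings.mean()) if len(spacings) else rise_hint

    basic = np.unique(arr.res_id[((res_names == "LYS") | (res_names == "ARG"))
                                 & np.isin(atom_names, ["NZ", "CZ"])])
    return FibrilModel(
        positions=arr.coord.astype(float), charges=charges,
        res_numbers=np.array(arr.res_id), res_names=res_names,
        layer_index=layer, atom_names=atom_names,
        roles=np.array(roles, dtype=str), n_layers=n_layers, rise=rise,
        site_list=[int(r) for r in basic],
    )


def write_glycan_pdb(glycan: GlycanModel, path) -> None:
    """Write the glycan as HETATM records (ring centroid, sulfurs, HCG O)."""
    records = []
    for u in glycan.units:
        resname = "SGN" if u.unit_kind == "glucosamine" else "IDS"
        records.append((u.unit_index, resname, "C1", u.ring_centroid, "C"))
        for sname in sorted(u.sulfurs):
            records.append((u.unit_index, resname, sname, u.sulfurs[sname], "S"))
    for h in glycan.hcgs:
        u = glycan.units[h.unit_index - 1]
        resname = "SGN" if u.unit_kind == "glucosamine" else "IDS"
        for j, o in enumerate(h.oxygen_positions, start=1):
            records.append((h.unit_index, resname, f"O{h.hcg_id}{j}", o, "O"))
    arr = struc.AtomArray(len(records))
    arr.coord = np.array([r[3] for r in records], dtype=np.float32)
    arr.chain_id = np.full(len(records), "X")
    arr.res_id = np.array([r[0] for r in records])
    arr.res_name = np.array([r[1] for r in records])
    arr.atom_name = np.array([r[2] for r in records])
    arr.element = np.array([r[4] for r in records])
    arr.hetero = np.ones(len(records), dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))
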