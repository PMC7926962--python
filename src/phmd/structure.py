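"""Structure measurements and conformational-state classification.

Covers the downstream analysis of the antibody simulations: optimal
(Kabsch) superposition, backbone reference RMSD (BRRMSD) over CDR regions,
the HCDR3-LCDR3 center distance (D3), extraction of low-PMF conformational
states, binder / non-binder classification, the 10 A key-residue rule, and
contact / hydrogen-bond binding-mode tables on antibody-antigen complexes.

PDB input/output goes through Biopython.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
}

#: atoms treated as backbone for RMSD selections (O deliberately excluded)
BACKBONE_ATOMS = ("N", "CA", "C")


class StructureError(ValueError):
    """Invalid structure input (missing chain, degenerate geometry, ...)."""


# ---------------------------------------------------------------------------
# CDR annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDRMap:
    """CDR residue ranges (1-based, inclusive) on chains H and L.

    Defaults are the standard ranges used throughout the analysis:
    HCDR1 30-35, HCDR2 50-66, HCDR3 99-110, LCDR1 24-34, LCDR2 50-56,
    LCDR3 89-97.
    """

    hcdr1: tuple = (30, 35)
    hcdr2: tuple = (50, 66)
    hcdr3: tuple = (99, 110)
    lcdr1: tuple = (24, 34)
    lcdr2: tuple = (50, 56)
    lcdr3: tuple = (89, 97)

    def regions(self) -> dict:
        """region name -> (chain, first, last)"""
        return {
            "HCDR1": ("H", *self.hcdr1),
            "HCDR2": ("H", *self.hcdr2),
            "HCDR3": ("H", *self.hcdr3),
            "LCDR1": ("L", *self.lcdr1),
            "LCDR2": ("L", *self.lcdr2),
            "LCDR3": ("L", *self.lcdr3),
        }

    def region_of(self, chain: str, resseq: int) -> Optional[str]:
        for name, (ch, lo, hi) in self.regions().items():
            if chain == ch and lo <= resseq <= hi:
                return name
        return None


#: default BRRMSD region selection (HCDR2-3 and LCDR1-3)
DEFAULT_BRRMSD_REGIONS = ("HCDR2", "HCDR3", "LCDR1", "LCDR2", "LCDR3")


# ---------------------------------------------------------------------------
# Structure container
# ---------------------------------------------------------------------------

class StructureModel:
    """Flat atom table (chain, 1-based residue number, name, element, xyz).

    Thin pandas-backed container; heavy lifting (PDB parsing/writing) is
    delegated to Biopython.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chain", "resseq", "resname", "atom_name", "element", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise StructureError(f"missing columns: {sorted(missing)}")
        df = df.reset_index(drop=True).copy()
        if (df["resseq"] <= 0).any():
            raise StructureError("residue numbers must be positive (1-based)")
        xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise StructureError("coordinates must be finite")
        if "mass" not in df.columns:
            df["mass"] = [
                _ELEMENT_MASSES.get(str(e).upper(), 12.011) for e in df["element"]
            ]
        if "is_backbone" not in df.columns:
            df["is_backbone"] = df["atom_name"].isin(BACKBONE_ATOMS)
        self.df = df

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "StructureModel":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def from_pdb(cls, path) -> "StructureModel":
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("model", str(path))
        records = []
        for model in structure:
            for chain in model:
                for residue in chain:
                    het, resseq, _ = residue.get_id()
                    for atom in residue:
                        x, y, z = atom.get_coord()
                        element = atom.element or atom.get_name()[0]
                        records.append(
                            {
                                "chain": chain.get_id(),
                                "resseq": int(resseq),
                                "resname": residue.get_resname().strip(),
                                "atom_name": atom.get_name().strip(),
                                "element": str(element).strip().upper(),
                                "x": float(x), "y": float(y), "z": float(z),
                            }
                        )
            break  # first model only
        return cls(pd.DataFrame(records))

    def to_pdb(self, path) -> None:
        from Bio.PDB import PDBIO
        from Bio.PDB.StructureBuilder import StructureBuilder

        builder = StructureBuilder()
        builder.init_structure("model")
        builder.init_model(0)
        current_chain = None
        current_res = None
        serial = 1
        for row in self.df.itertuples(index=False):
            if row.chain != current_chain:
                builder.init_chain(str(row.chain))
                builder.init_seg("    ")
                current_chain = row.chain
                current_res = None
            key = (row.chain, row.resseq)
            if key != current_res:
                builder.init_residue(str(row.resname), " ", int(row.resseq), " ")
                current_res = key
            builder.init_atom(
                str(row.atom_name),
                np.array([row.x, row.y, row.z], dtype=float),
                0.0, 1.0, " ",
                str(row.atom_name).ljust(3),
                serial,
                str(row.element),
            )
            serial += 1
        io = PDBIO()
        io.set_structure(builder.get_structure())
        io.save(str(path))

    # -- selections ---------------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def chains(self) -> list:
        return sorted(self.df["chain"].unique())

    def select(
        self,
        chain: Optional[str] = None,
        resseq_range: Optional[tuple] = None,
        backbone_only: bool = False,
        heavy_only: bool = False,
    ) -> pd.DataFrame:
        m = pd.Series(True, index=self.df.index)
        if chain is not None:
            m &= self.df["chain"] == chain
        if resseq_range is not None:
            m &= self.df["resseq"].between(resseq_range[0], resseq_range[1])
        if backbone_only:
            m &= self.df["is_backbone"]
        if heavy_only:
            m &= self.df["element"] != "H"
        return self.df[m]

    def region_atoms(self, cdr_map: CDRMap, region: str, backbone_only: bool = False) -> pd.DataFrame:
        chain, lo, hi = cdr_map.regions()[region]
        return self.select(chain=chain, resseq_range=(lo, hi), backbone_only=backbone_only)

    def residue_com(self, chain: str, resseq: int) -> np.ndarray:
        sub = self.df[(self.df["chain"] == chain) & (self.df["resseq"] == resseq)]
        if sub.empty:
            raise StructureError(f"no atoms for residue {chain}:{resseq}")
        w = sub["mass"].to_numpy(dtype=float)
        return (sub[["x", "y", "z"]].to_numpy(dtype=float) * w[:, None]).sum(axis=0) / w.sum()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        df = self.df.copy()
        xyz = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        df[["x", "y", "z"]] = xyz
        return StructureModel(df)


# ---------------------------------------------------------------------------
# Superposition and reaction coordinates
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with ``rotation`` proper
    (determinant +1) and rmsd minimal over all rigid transforms:
    x_fit = x_mobile @ rotation.T + translation.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise StructureError("selections must be matching (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise StructureError("need at least 3 atoms for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    mc = (mob * w[:, None]).sum(axis=0) / wsum
    rc = (ref * w[:, None]).sum(axis=0) / wsum
    a = mob - mc
    b = ref - rc
    if np.linalg.matrix_rank(a) < 2:
        raise StructureError("degenerate (collinear) geometry")
    rot, rssd = Rotation.align_vectors(b, a, weights=w)
    rmat = rot.as_matrix()
    translation = rc - mc @ rmat.T
    fitted = a @ rmat.T
    rmsd = math.sqrt(float((w[:, None] * (fitted - b) ** 2).sum() / wsum))
    return rmat, translation, rmsd


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid transforms."""
    return kabsch_superpose(mobile, reference)[2]


def brrmsd(
    frame: "StructureModel | np.ndarray",
    reference: "StructureModel | np.ndarray",
    cdr_map: Optional[CDRMap] = None,
    regions: Sequence[str] = DEFAULT_BRRMSD_REGIONS,
) -> float:
    """Backbone reference RMSD of the CDR regions.

    For :class:`StructureModel` inputs, selects backbone atoms (N, CA, C)
    of the given regions (default HCDR2-3 + LCDR1-3), superposes the frame
    onto the reference over that selection, and returns the RMSD over the
    same atoms.  Plain coordinate arrays are compared directly (bead
    models: every bead is backbone).
    """
    if isinstance(frame, StructureModel):
        cdr_map = cdr_map or CDRMap()
        sel_m = []
        sel_r = []
        for region in sorted(regions):
            sel_m.append(frame.region_atoms(cdr_map, region, backbone_only=True)[["x", "y", "z"]].to_numpy())
            sel_r.append(reference.region_atoms(cdr_map, region, backbone_only=True)[["x", "y", "z"]].to_numpy())
        mob = np.vstack(sel_m)
        ref = np.vstack(sel_r)
    else:
        mob = np.asarray(frame, dtype=float).reshape(-1, 3)
        ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    return superposed_rmsd(mob, ref)


def d3_distance(frame: StructureModel, cdr_map: Optional[CDRMap] = None) -> float:
    """Distance between the mass-weighted centers of HCDR3 and LCDR3, A."""
    cdr_map = cdr_map or CDRMap()
    coms = []
    for region in ("HCDR3", "LCDR3"):
        sub = frame.region_atoms(cdr_map, region)
        if sub.empty:
            raise StructureError(f"region {region} has no atoms")
        w = sub["mass"].to_numpy(dtype=float)
        coms.append((sub[["x", "y", "z"]].to_numpy(dtype=float) * w[:, None]).sum(axis=0) / w.sum())
    return float(np.linalg.norm(coms[0] - coms[1]))


# mini-Fab (bead model) equivalents -----------------------------------------

def minifab_brrmsd(model, coords: np.ndarray, regions=("HCDR3-like", "LCDR3-like")) -> float:
    """BRRMSD of the mini-Fab loop beads against the model reference."""
    idx = np.concatenate([model.loops[r] for r in sorted(regions)])
    xyz = np.asarray(coords).reshape(-1, 3)
    return superposed_rmsd(xyz[idx], model.coords0[idx])


def minifab_d3(model, coords: Optional[np.ndarray] = None) -> float:
    """Distance between the mass-weighted loop centers of the mini-Fab."""
    a = model.loop_com("HCDR3-like", coords)
    b = model.loop_com("LCDR3-like", coords)
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# State tables: extraction, filtering, classification
# ---------------------------------------------------------------------------

STATE_COLUMNS = ("brrmsd", "d3", "pmf")


def extract_states(grid, pmf_cutoff: float = 50.0) -> pd.DataFrame:
    """Low-free-energy conformational states from a normalized PMF grid.

    Keeps occupied, reliable bins with PMF strictly below ``pmf_cutoff``
    (default 50 kcal/mol) and returns rows (brrmsd, d3, pmf) at the bin
    centers, sorted by (brrmsd, d3).
    """
    table = grid.to_frame()
    keep = table["reliable"] & table["pmf"].notna() & (table["pmf"] < pmf_cutoff)
    out = table.loc[keep, ["rc1_center", "rc2_center", "pmf"]].rename(
        columns={"rc1_center": "brrmsd", "rc2_center": "d3"}
    )
    return out.sort_values(["brrmsd", "d3"]).reset_index(drop=True)


def filter_states(
    table: pd.DataFrame,
    pmf_cutoff: Optional[float] = None,
    brrmsd_range: Optional[tuple] = None,
    d3_range: Optional[tuple] = None,
) -> pd.DataFrame:
    """Filter a state table: strict PMF cutoff, inclusive coordinate ranges."""
    m = pd.Series(True, index=table.index)
    if pmf_cutoff is not None:
        m &= table["pmf"] < pmf_cutoff
    if brrmsd_range is not None:
        m &= table["brrmsd"].between(brrmsd_range[0], brrmsd_range[1])
    if d3_range is not None:
        m &= table["d3"].between(d3_range[0], d3_range[1])
    return table[m].reset_index(drop=True)


@dataclass(frozen=True)
class ClassificationCounts:
    binder_like: int
    non_binder_like: int
    indeterminate: int

    @property
    def total(self) -> int:
        return self.binder_like + self.non_binder_like + self.indeterminate


def classify_states(
    table: pd.DataFrame, bind_max: float = 1.5, nonbind_min: float = 2.5
) -> ClassificationCounts:
    """Binder-like / non-binder-like split of a state table.

    A state is binder-like when its BRRMSD is at or below ``bind_max``
    (geometry close enough to the reference to retain antigen binding),
    non-binder-like at or above ``nonbind_min``, indeterminate between.
    """
    if len(table) == 0:
        return ClassificationCounts(0, 0, 0)
    b = table["brrmsd"].to_numpy(dtype=float)
    binder = int(np.sum(b <= bind_max))
    non = int(np.sum(b >= nonbind_min))
    return ClassificationCounts(binder, non, len(table) - binder - non)


def load_example_state_table(ph: float) -> pd.DataFrame:
    """Packaged worked-example conformational state tables.

    Observed (BRRMSD, D3, PMF) states of an engineered pH-switchable
    anti-TNF-alpha antibody from enhanced-sampling constant-pH simulations,
    at pH 6.0 or 7.4; shipped verbatim as printed (including one duplicated
    row index in the pH 6.0 table).
    """
    key = f"{ph:.1f}"
    if key not in ("6.0", "7.4"):
        raise ValueError("example state tables exist for pH 6.0 and 7.4")
    with resources.files("phmd.data").joinpath(f"state_table_ph{key}.csv").open() as fh:
        df = pd.read_csv(fh)
    return df[["brrmsd", "d3", "pmf"]].copy()


# ---------------------------------------------------------------------------
# Key-residue rule
# ---------------------------------------------------------------------------

def key_residue_pairs(
    structure: StructureModel, cdr_map: Optional[CDRMap] = None, cutoff: float = 10.0
) -> pd.DataFrame:
    """Cross-CDR residue pairs closer than ``cutoff`` (strict, default 10 A).

    Distance is between residue centers of mass; pairs must come from two
    *different* CDR regions.  Output is symmetric-free (each unordered pair
    appears once) and sorted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    cdr_map = cdr_map or CDRMap()
    residues = []
    for region, (chain, lo, hi) in cdr_map.regions().items():
        sub = structure.select(chain=chain, resseq_range=(lo, hi))
        for resseq in sorted(sub["resseq"].unique()):
            residues.append((region, chain, int(resseq), structure.residue_com(chain, int(resseq))))
    rows = []
    for i in range(len(residues)):
        ri, ci, ni, comi = residues[i]
        for j in range(i + 1, len(residues)):
            rj, cj, nj, comj = residues[j]
            if ri == rj:
                continue
            d = float(np.linalg.norm(comi - comj))
            if d < cutoff:
                rows.append(
                    {"region1": ri, "chain1": ci, "resseq1": ni,
                     "region2": rj, "chain2": cj, "resseq2": nj, "distance": d}
                )
    return pd.DataFrame(
        rows, columns=["region1", "chain1", "resseq1", "region2", "chain2", "resseq2", "distance"]
    ).sort_values(["region1", "resseq1", "region2", "resseq2"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Binding modes (contacts + hydrogen bonds against antigen chain A)
# ---------------------------------------------------------------------------

@dataclass
class BindingModeRecord:
    """Contacting residues of one antibody region (Null when empty)."""

    region: str
    residues: list = field(default_factory=list)   # (resname, resseq, hbond_flag)

    @property
    def is_null(self) -> bool:
        return not self.residues

    def format(self) -> str:
        if self.is_null:
            return "Null"
        parts = []
        for resname, resseq, hb in self.residues:
            label = f"{resname.capitalize()}{resseq}"
            parts.append(label + (" (HB)" if hb else ""))
        return ", ".join(parts)


_DONOR_ACCEPTOR_ELEMENTS = ("N", "O")


def _hbond_between(res_a: pd.DataFrame, res_b: pd.DataFrame,
                   max_da: float, min_angle_deg: float, max_da_no_h: float) -> bool:
    """Hydrogen bond between any donor/acceptor heavy atoms of two residues.

    With hydrogens present on the donor: D-A <= max_da and D-H...A angle
    >= min_angle_deg; otherwise the distance-only criterion D-A <= max_da_no_h.
    """
    for donor_res, acceptor_res in ((res_a, res_b), (res_b, res_a)):
        donors = donor_res[donor_res["element"].isin(_DONOR_ACCEPTOR_ELEMENTS)]
        acceptors = acceptor_res[acceptor_res["element"].isin(_DONOR_ACCEPTOR_ELEMENTS)]
        if donors.empty or acceptors.empty:
            continue
        hydrogens = donor_res[donor_res["element"] == "H"][["x", "y", "z"]].to_numpy(dtype=float)
        d_xyz = donors[["x", "y", "z"]].to_numpy(dtype=float)
        a_xyz = acceptors[["x", "y", "z"]].to_numpy(dtype=float)
        for d in d_xyz:
            # hydrogens covalently bound to this donor (<= 1.2 A)
            attached = hydrogens[np.linalg.norm(hydrogens - d, axis=1) <= 1.2] if hydrogens.size else np.empty((0, 3))
            for a in a_xyz:
                da = float(np.linalg.norm(a - d))
                if attached.shape[0] > 0:
                    if da > max_da:
                        continue
                    for h in attached:
                        v1 = d - h
                        v2 = a - h
                        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                        angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                        if angle >= min_angle_deg:
                            return True
                else:
                    if da <= max_da_no_h:
                        return True
    return False


def binding_modes(
    complex_structure: StructureModel,
    cdr_map: Optional[CDRMap] = None,
    contact_cutoff: float = 4.0,
    hbond_distance: float = 3.5,
    hbond_angle: float = 120.0,
    hbond_distance_no_h: float = 3.2,
) -> list[BindingModeRecord]:
    """Per-region contact / hydrogen-bond table of an antibody-antigen complex.

    An antibody residue is *contacting* when any of its heavy atoms lies
    within ``contact_cutoff`` (default 4 A, inclusive) of an antigen heavy
    atom.  Contacting residues are grouped by CDR region, with "other"
    buckets for framework residues of each chain.
    """
    cdr_map = cdr_map or CDRMap()
    for chain in ("H", "L", "A"):
        if chain not in complex_structure.chains:
            raise StructureError(f"missing chain {chain}")
    antigen_heavy = complex_structure.select(chain="A", heavy_only=True)
    ag_xyz = antigen_heavy[["x", "y", "z"]].to_numpy(dtype=float)
    ag_res = antigen_heavy[["resseq"]].to_numpy().ravel()

    region_order = ["HCDR1", "HCDR2", "HCDR3", "LCDR1", "LCDR2", "LCDR3",
                    "other (heavy chain)", "other (light chain)"]
    records = {name: BindingModeRecord(region=name) for name in region_order}

    for chain in ("H", "L"):
        sub = complex_structure.select(chain=chain)
        for resseq in sorted(sub["resseq"].unique()):
            res = sub[sub["resseq"] == resseq]
            heavy = res[res["element"] != "H"]
            xyz = heavy[["x", "y", "z"]].to_numpy(dtype=float)
            dmin_per_ag = np.sqrt(
                ((xyz[:, None, :] - ag_xyz[None, :, :]) ** 2).sum(axis=2)
            )
            contact_mask = dmin_per_ag.min(axis=0) <= contact_cutoff
            if not contact_mask.any():
                continue
            # hydrogen bond against any contacting antigen residue
            hb = False
            for ag_resseq in np.unique(ag_res[contact_mask]):
                ag_residue = complex_structure.df[
                    (complex_structure.df["chain"] == "A")
                    & (complex_structure.df["resseq"] == ag_resseq)
                ]
                if _hbond_between(res, ag_residue, hbond_distance, hbond_angle, hbond_distance_no_h):
                    hb = True
                    break
            region = cdr_map.region_of(chain, int(resseq))
            if region is None:
                region = "other (heavy chain)" if chain == "H" else "other (light chain)"
            resname = str(res["resname"].iloc[0])
            records[region].residues.append((resname, int(resseq), hb))
    return [records[name] for name in region_order]
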