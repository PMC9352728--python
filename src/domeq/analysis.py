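"""Post-hoc analysis of multi-state ensembles.

Conformers are sorted into compact and extended states by presence or
absence of an interdomain heavy-atom contact; per-residue RMSD profiles
between two sets of conformers are computed between mean structures
after least-squares superposition on a reference core, with the
uncertainty of the difference taken as the square root of the summed
per-set variances; restraint-set overlaps are reported per restraint
kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .restraints import Conformer, DistanceRestraint, TwoStateEnsemble

__all__ = [
    "DOMAIN_A_RESIDUES",
    "DOMAIN_B_RESIDUES",
    "StateSortedEnsemble",
    "classify_states",
    "contact_sensitivity",
    "rmsd_profile",
    "restraint_overlap",
]

#: Default two-domain residue ranges (small binding domain, catalytic domain).
DOMAIN_A_RESIDUES = range(1, 40)
DOMAIN_B_RESIDUES = range(50, 164)


@dataclass
class StateSortedEnsemble:
    """Exhaustive, disjoint partition of conformers by interdomain contact."""

    compact: list[Conformer]
    extended: list[Conformer]
    contact_cutoff: float

    @property
    def populations(self) -> tuple[float, float]:
        n = len(self.compact) + len(self.extended)
        if n == 0:
            raise ValueError("empty ensemble")
        return (len(self.compact) / n, len(self.extended) / n)


def _domain_coords(conf: Conformer, residues: range) -> np.ndarray:
    xyz = [v for (resi, _), v in conf.coords.items() if resi in residues]
    return np.array(xyz)


def min_interdomain_distance(
    conf: Conformer,
    domain_a_residues: range = DOMAIN_A_RESIDUES,
    domain_b_residues: range = DOMAIN_B_RESIDUES,
) -> float:
    """Minimum heavy-atom distance between the two domains (A)."""
    a = _domain_coords(conf, domain_a_residues)
    b = _domain_coords(conf, domain_b_residues)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("conformer does not contain both domains")
    return float(cdist(a, b).min())


def classify_states(
    conformers: "list[Conformer] | TwoStateEnsemble",
    contact_cutoff: float = 5.0,
    domain_a_residues: range = DOMAIN_A_RESIDUES,
    domain_b_residues: range = DOMAIN_B_RESIDUES,
) -> StateSortedEnsemble:
    """Sort conformers by interdomain contact.

    A conformer is compact iff any interdomain heavy-atom pair lies
    closer than ``contact_cutoff`` (default 5 A), otherwise extended.
    """
    if isinstance(conformers, TwoStateEnsemble):
        conformers = conformers.conformers
    compact, extended = [], []
    for conf in conformers:
        d = min_interdomain_distance(conf, domain_a_residues, domain_b_residues)
        (compact if d < contact_cutoff else extended).append(conf)
    return StateSortedEnsemble(compact, extended, contact_cutoff)


def contact_sensitivity(
    conformers: "list[Conformer] | TwoStateEnsemble",
    cutoffs: tuple[float, ...] = (4.0, 5.0, 6.0),
    **kwargs,
) -> pd.DataFrame:
    """Compact fraction as a function of the contact cutoff (4-6 A)."""
    rows = []
    for c in cutoffs:
        sorted_ens = classify_states(conformers, contact_cutoff=c, **kwargs)
        rows.append({"cutoff_A": c, "p_compact": sorted_ens.populations[0]})
    return pd.DataFrame(rows)


def _common_atoms(sets: list[list[Conformer]]) -> list:
    keys = None
    for confs in sets:
        for conf in confs:
            k = set(conf.coords)
            keys = k if keys is None else keys & k
    return sorted(keys)


def _superpose_all(
    conformers: list[Conformer], core_atoms: list, reference: np.ndarray
) -> list[Conformer]:
    """Least-squares (Kabsch) superposition of each conformer's core onto
    the reference core coordinates."""
    out = []
    ref_centered = reference - reference.mean(axis=0)
    for conf in conformers:
        core = np.array([conf.coords[k] for k in core_atoms])
        centroid = core.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, core - centroid)
        moved = {
            k: rot.apply(v - centroid) + reference.mean(axis=0)
            for k, v in conf.coords.items()
        }
        out.append(Conformer(moved, dict(conf.res_names)))
    return out


def rmsd_profile(
    set_a: list[Conformer],
    set_b: list[Conformer],
    superposition_residues: "range | list[int] | None" = None,
    superposition_atoms: tuple[str, ...] = ("CA",),
) -> pd.DataFrame:
    """Per-residue RMSD between the mean structures of two conformer sets.

    Both sets are superposed onto a common reference core (default: the
    larger domain's backbone atoms of the first conformer of ``set_a``),
    mean coordinates are computed per set, and the per-residue RMSD over
    all shared heavy atoms between the two mean structures is returned
    together with the uncertainty sqrt(var_a + var_b), where var is the
    within-set mean squared scatter about the mean structure.

    Returns a DataFrame with columns residue, rmsd_A, uncertainty_A.
    Atoms present in only one set are excluded (their names are listed
    in ``df.attrs['excluded_atoms']``).
    """
    if superposition_residues is None:
        superposition_residues = DOMAIN_B_RESIDUES
    all_keys_a = set().union(*(set(c.coords) for c in set_a))
    all_keys_b = set().union(*(set(c.coords) for c in set_b))
    excluded = sorted(all_keys_a ^ all_keys_b)
    atoms = _common_atoms([set_a, set_b])
    core = [k for k in atoms if k[0] in superposition_residues and k[1] in superposition_atoms]
    if len(core) < 3:
        raise ValueError("superposition core needs at least 3 atoms")
    # canonical reference: iterated mean core over the union of both sets,
    # which makes the profile exactly symmetric under swapping the sets
    everyone = list(set_a) + list(set_b)
    reference = np.mean([[c.coords[k] for k in core] for c in everyone], axis=0)
    for _ in range(5):
        aligned = _superpose_all(everyone, core, reference)
        reference = np.mean([[c.coords[k] for k in core] for c in aligned], axis=0)
    sup_a = _superpose_all(set_a, core, reference)
    sup_b = _superpose_all(set_b, core, reference)

    coords_a = np.array([[c.coords[k] for k in atoms] for c in sup_a])
    coords_b = np.array([[c.coords[k] for k in atoms] for c in sup_b])
    mean_a = coords_a.mean(axis=0)
    mean_b = coords_b.mean(axis=0)
    var_a = ((coords_a - mean_a) ** 2).sum(axis=2).mean(axis=0)
    var_b = ((coords_b - mean_b) ** 2).sum(axis=2).mean(axis=0)
    sq_dev = ((mean_a - mean_b) ** 2).sum(axis=1)

    residues = sorted({k[0] for k in atoms})
    rows = []
    for resi in residues:
        mask = np.array([k[0] == resi for k in atoms])
        rows.append({
            "residue": resi,
            "rmsd_A": float(np.sqrt(sq_dev[mask].mean())),
            "uncertainty_A": float(np.sqrt(var_a[mask].mean() + var_b[mask].mean())),
        })
    df = pd.DataFrame(rows)
    df.attrs["excluded_atoms"] = excluded
    df.attrs["superposition_residues"] = list(superposition_residues)
    df.attrs["superposition_atoms"] = list(superposition_atoms)
    return df


def restraint_overlap(
    set_a: list[DistanceRestraint], set_b: list[DistanceRestraint]
) -> pd.DataFrame:
    """Shared fraction of restraints per kind between two restraint sets.

    Restraint identity is the order-normalized (atom_a, atom_b, kind)
    triple. Reports |A n B| / |A| and |A n B| / |B| per kind; empty sets
    give NA.
    """
    kinds = sorted({r.kind for r in set_a} | {r.kind for r in set_b})
    rows = []
    for kind in kinds:
        ids_a = {r.pair_id() for r in set_a if r.kind == kind}
        ids_b = {r.pair_id() for r in set_b if r.kind == kind}
        shared = len(ids_a & ids_b)
        rows.append({
            "kind": kind,
            "n_a": len(ids_a),
            "n_b": len(ids_b),
            "n_shared": shared,
            "frac_of_a": shared / len(ids_a) if ids_a else float("nan"),
            "frac_of_b": shared / len(ids_b) if ids_b else float("nan"),
        })
    return pd.DataFrame(rows)
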