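"""Protein-DNA contact distances and the three-rule descriptor filter.

Candidate descriptors are distances from the charged side-chain tip of
lysine (Nζ) or arginine (Cζ) to a DNA backbone phosphorus atom.  A candidate
pool is reduced to a working descriptor set by three rules applied in order:

(i)   presence — the contact is formed (distance <= cutoff) in at least half
      of the frames of at least one state;
(ii)  separation — the between-state mean shift exceeds two standard
      deviations;
(iii) redundancy — at most one contact is kept per (residue, base-pair)
      group, the one with the largest rule-(ii) margin.

Every rejected descriptor records the *first* rule that failed, so the
report doubles as an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AtomResolutionError, ContactDefinitionError, InputError, SchemaError
from .tables import DescriptorTable

__all__ = [
    "ContactDefinition",
    "FilterReport",
    "anchor_atom_for",
    "compute_contact_distances",
    "filter_descriptors",
]

_ANCHORS = {"LYS": "NZ", "ARG": "CZ"}
_STRANDS = ("primer", "template")


def anchor_atom_for(res_name: str) -> str:
    """Side-chain anchor atom by residue type (Nζ for Lys, Cζ for Arg)."""
    try:
        return _ANCHORS[res_name.upper()]
    except KeyError:
        raise ContactDefinitionError(
            f"no anchor atom defined for residue type {res_name!r}"
        ) from None


@dataclass(frozen=True)
class ContactDefinition:
    """One protein-residue-to-phosphate distance descriptor.

    ``dna_res_id`` is the residue id of the nucleotide whose P atom is
    measured; ``base_pair_index`` is the duplex position label used for the
    redundancy grouping.
    """

    descriptor_id: str
    protein_res_name: str
    protein_res_id: int
    protein_chain: str
    strand: str
    base_pair_index: int
    dna_chain: str
    dna_res_id: int
    anchor_atom_name: str | None = None

    def __post_init__(self):
        if self.strand not in _STRANDS:
            raise ContactDefinitionError(f"strand must be one of {_STRANDS}")
        expected = anchor_atom_for(self.protein_res_name)
        if self.anchor_atom_name is not None and self.anchor_atom_name != expected:
            raise ContactDefinitionError(
                f"{self.descriptor_id}: {self.protein_res_name} anchors at "
                f"{expected}, not {self.anchor_atom_name}"
            )

    @property
    def anchor(self) -> str:
        return self.anchor_atom_name or anchor_atom_for(self.protein_res_name)

    @property
    def group_key(self) -> tuple:
        return (f"{self.protein_res_name}{self.protein_res_id}", f"bp{self.base_pair_index}")


def _as_stack(structure_frames):
    import biotite.structure as struc

    if isinstance(structure_frames, (str,)) or hasattr(structure_frames, "__fspath__"):
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(structure_frames)
        structure_frames = pdb.get_structure()  # AtomArrayStack over all models
    if isinstance(structure_frames, struc.AtomArray):
        structure_frames = struc.stack([structure_frames])
    return structure_frames


def _locate(stack, chain: str, res_id: int, atom_name: str) -> np.ndarray:
    mask = (
        (stack.chain_id == chain)
        & (stack.res_id == res_id)
        & (stack.atom_name == atom_name)
    )
    idx = np.flatnonzero(mask)
    if len(idx) != 1:
        raise AtomResolutionError(
            f"atom {atom_name} of residue {res_id} chain {chain}: "
            f"{len(idx)} matches (need exactly 1)"
        )
    return idx[0]


def compute_contact_distances(
    structure_frames, contact_definitions: list[ContactDefinition]
) -> DescriptorTable:
    """Euclidean anchor-to-phosphate distances (Å), one column per contact.

    ``structure_frames`` may be a PDB path (single- or multi-model) or a
    biotite ``AtomArray``/``AtomArrayStack``; frame order is preserved.
    """
    if not contact_definitions:
        raise InputError("no contact definitions given")
    stack = _as_stack(structure_frames)
    coords = stack.coord  # (n_models, n_atoms, 3)
    cols = {}
    for cd in contact_definitions:
        i = _locate(stack, cd.protein_chain, cd.protein_res_id, cd.anchor)
        res_name = str(stack.res_name[i])
        if res_name.upper() != cd.protein_res_name.upper():
            raise ContactDefinitionError(
                f"{cd.descriptor_id}: residue {cd.protein_res_id} in chain "
                f"{cd.protein_chain} is {res_name}, definition says {cd.protein_res_name}"
            )
        j = _locate(stack, cd.dna_chain, cd.dna_res_id, "P")
        d = np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=-1)
        cols[cd.descriptor_id] = d
    df = pd.DataFrame(cols)
    return DescriptorTable(df, {cd.descriptor_id: cd for cd in contact_definitions})


# ---------------------------------------------------------------------------
# the three-rule filter

class FilterReport:
    """Per-descriptor audit of the three-rule filter."""

    def __init__(self, records: pd.DataFrame):
        self.records = records

    @property
    def retained_ids(self) -> list[str]:
        return list(self.records.loc[self.records.retained, "descriptor_id"])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FilterReport":
        return cls(pd.read_csv(path))


def _meta_group_key(meta, descriptor_id: str) -> tuple:
    if meta is None:
        return (descriptor_id, "")
    if hasattr(meta, "group_key"):
        return meta.group_key
    res = getattr(meta, "residue_label", None)
    bp = getattr(meta, "base_pair_label", None)
    if isinstance(meta, dict):
        res = meta.get("residue_label", res)
        bp = meta.get("base_pair_label", bp)
    if res is None or bp is None:
        return (descriptor_id, "")
    return (res, bp)


def filter_descriptors(
    table_state_a: DescriptorTable,
    table_state_b: DescriptorTable,
    presence_cutoff: float = 6.0,
    presence_fraction: float = 0.5,
    sd_mode: str = "max",
) -> tuple[list[str], FilterReport]:
    """Apply the presence / separation / redundancy rules in order.

    ``sd_mode``: "max" compares the mean shift against 2*max(SD_A, SD_B)
    (conservative default); "pooled" uses the root-mean-square of the two SDs.
    """
    if len(table_state_a) == 0 or len(table_state_b) == 0:
        raise InputError("state tables must be nonempty")
    ids = table_state_a.descriptor_ids
    if ids != table_state_b.descriptor_ids:
        raise SchemaError("state tables carry different descriptor inventories")
    if sd_mode not in ("max", "pooled"):
        raise SchemaError(f"unknown sd_mode {sd_mode!r}")

    A = table_state_a.values()
    B = table_state_b.values()
    pres_a = (A <= presence_cutoff).mean(axis=0)
    pres_b = (B <= presence_cutoff).mean(axis=0)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    sd_a, sd_b = A.std(axis=0), B.std(axis=0)
    if sd_mode == "max":
        sd_ref = np.maximum(sd_a, sd_b)
    else:
        sd_ref = np.sqrt(0.5 * (sd_a**2 + sd_b**2))
    shift = np.abs(mean_a - mean_b)
    margin = shift - 2.0 * sd_ref

    pass_i = (pres_a >= presence_fraction) | (pres_b >= presence_fraction)
    pass_ii = shift > 2.0 * sd_ref

    group_keys = [
        _meta_group_key(table_state_a.metadata.get(c), c) for c in ids
    ]

    removing = np.array(["none"] * len(ids), dtype=object)
    removing[~pass_i] = "presence"
    removing[pass_i & ~pass_ii] = "separation"

    # rule iii among survivors of i and ii, per group: keep largest margin,
    # lexicographic id as the deterministic tie-break
    survivors = pass_i & pass_ii
    best_in_group: dict[tuple, tuple] = {}
    for k, cid in enumerate(ids):
        if not survivors[k]:
            continue
        key = group_keys[k]
        cand = (-margin[k], cid)
        if key not in best_in_group or cand < best_in_group[key][0]:
            best_in_group[key] = (cand, k)
    keep = np.zeros(len(ids), dtype=bool)
    for (_, k) in best_in_group.values():
        keep[k] = True
    removing[survivors & ~keep] = "dedup"

    records = pd.DataFrame(
        {
            "descriptor_id": ids,
            "retained": keep,
            "removing_rule": removing,
            "presence_fraction_a": pres_a,
            "presence_fraction_b": pres_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "sd_a": sd_a,
            "sd_b": sd_b,
            "margin": margin,
            "group_residue": [g[0] for g in group_keys],
            "group_base_pair": [g[1] for g in group_keys],
        }
    )
    return [ids[k] for k in np.flatnonzero(keep)], FilterReport(records)
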