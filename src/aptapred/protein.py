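"""Protein sequence encoders and feature-matrix assembly.

AAC is the vector of 20 residue frequencies. PseAAC augments it with
``lambda`` sequence-order correlation tiers computed from a group of three
physicochemical properties, each property standardized to mean 0 and
population variance 1 across the 20 residues before use. The tier at lag d
averages, over all residue pairs (i, i+d), the mean squared difference of
the three standardized property values. The final vector of length
20 + lambda is normalized so its components sum to 1, with the tier part
weighted by ``omega``.

``build_feature_matrix`` concatenates an aptamer k-mer block with one
50-entry PseAAC block per selected property group (A..H) for every pair in
an interaction dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .aptamer import FeatureVector, KmerSpec
from .seqio import InteractionDataset, ProteinSequence

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_INDEX = {r: i for i, r in enumerate(RESIDUES)}

GROUP_NAMES = "ABCDEFGH"


class PropertyTableError(ValueError):
    pass


@dataclass
class PropertyTable:
    """Per-residue physicochemical property values, grouped in triples.

    ``values`` is a (20, n_properties) frame indexed by residue; ``groups``
    maps group name -> list of exactly 3 property names.
    """

    values: pd.DataFrame
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if list(self.values.index) != list(RESIDUES):
            raise PropertyTableError(
                "property table must have exactly the 20 standard residues "
                f"in order {RESIDUES}"
            )
        for name, props in self.groups.items():
            if len(props) != 3:
                raise PropertyTableError(f"group {name!r} must have exactly 3 properties")
            missing = [p for p in props if p not in self.values.columns]
            if missing:
                raise PropertyTableError(f"group {name!r} references unknown properties {missing}")

    @property
    def property_names(self) -> list[str]:
        return list(self.values.columns)

    def standardized(self) -> "PropertyTable":
        return standardize_properties(self)

    def group_matrix(self, group: str) -> np.ndarray:
        """(20, 3) array of the group's property values in listed order."""
        if group not in self.groups:
            raise KeyError(f"unknown property group {group!r}")
        return self.values[self.groups[group]].to_numpy(dtype=float)


def load_property_table(
    properties_path: str | Path | None = None,
    groups_path: str | Path | None = None,
) -> PropertyTable:
    """Load the packaged default table, or a user-supplied replacement.

    ``properties.csv``: residue rows x property columns, first column
    ``residue``. ``property_groups.csv``: columns group, property_1..3.
    """
    if properties_path is None:
        properties_path = resources.files("aptapred.data") / "properties.csv"
    if groups_path is None:
        groups_path = resources.files("aptapred.data") / "property_groups.csv"
    with resources.as_file(properties_path) if not isinstance(properties_path, (str, Path)) else _noop(properties_path) as p:
        values = pd.read_csv(p, index_col="residue")
    with resources.as_file(groups_path) if not isinstance(groups_path, (str, Path)) else _noop(groups_path) as p:
        gdf = pd.read_csv(p)
    values = values.reindex(list(RESIDUES))
    if values.isna().any().any():
        raise PropertyTableError("property table is missing residues or has NaN values")
    groups = {
        str(row["group"]): [row["property_1"], row["property_2"], row["property_3"]]
        for _, row in gdf.iterrows()
    }
    return PropertyTable(values=values, groups=groups)


class _noop:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def standardize_properties(table: PropertyTable) -> PropertyTable:
    """Standardize every property to mean 0, population variance 1.

    The divisor is the population standard deviation over the 20 residues
    (denominator 20, not 19). A constant property has zero spread and is
    rejected by name.
    """
    cached = getattr(table, "_standardized_cache", None)
    if cached is not None:
        return cached
    raw = table.values
    mean = raw.mean(axis=0)
    std = np.sqrt(((raw - mean) ** 2).mean(axis=0))
    constant = std[std == 0].index.tolist()
    if constant:
        raise PropertyTableError(
            f"properties {constant} are constant across residues (zero denominator)"
        )
    result = PropertyTable(values=(raw - mean) / std, groups=dict(table.groups))
    object.__setattr__(result, "_standardized_cache", result)  # idempotent
    object.__setattr__(table, "_standardized_cache", result)
    return result


@dataclass(frozen=True)
class PseAACSpec:
    """PseAAC parameters: correlation depth lambda, tier weight omega, group."""

    lam: int = 30
    omega: float = 0.05
    group: str = "A"

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")


def aac_vector(seq: ProteinSequence | str) -> FeatureVector:
    """20 residue frequencies in ACDEFGHIKLMNPQRSTVWY order; sums to 1."""
    seq_id, residues = _residues(seq)
    if not residues:
        raise ValueError(f"sequence {seq_id!r} is empty")
    counts = np.zeros(20)
    for ch in residues:
        idx = _RESIDUE_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"sequence {seq_id!r}: invalid residue {ch!r}")
        counts[idx] += 1
    return FeatureVector(
        names=tuple(f"aac_{r}" for r in RESIDUES),
        values=counts / len(residues),
    )


def theta_tier(seq: ProteinSequence | str, lag: int, group_values: np.ndarray) -> float:
    """Sequence-order correlation factor at the given lag.

    ``group_values`` is the (20, 3) standardized property matrix. Averages
    the mean squared standardized-property difference over all residue
    pairs separated by ``lag``.
    """
    seq_id, residues = _residues(seq)
    L = len(residues)
    if not 1 <= lag < L:
        raise ValueError(f"sequence {seq_id!r}: lag must satisfy 1 <= lag < L={L}, got {lag}")
    idx = np.fromiter((_RESIDUE_INDEX[ch] for ch in residues), dtype=int, count=L)
    props = group_values[idx]  # (L, 3)
    diffs = props[lag:] - props[:-lag]
    return float(np.mean(np.sum(diffs**2, axis=1) / 3.0))


def pseaac_vector(
    seq: ProteinSequence | str,
    spec: PseAACSpec,
    table: PropertyTable | None = None,
) -> FeatureVector:
    """(20 + lambda)-dimensional PseAAC vector for one property group.

    Components are non-negative and sum to 1: the first 20 carry the
    composition effect, the last lambda the omega-weighted sequence-order
    tiers. Requires L > lambda.
    """
    if table is None:
        table = _default_table()
    seq_id, residues = _residues(seq)
    L = len(residues)
    if L <= spec.lam:
        raise ValueError(
            f"sequence {seq_id!r}: length {L} must exceed lambda={spec.lam} for PseAAC"
        )
    std = standardize_properties(table)
    gvals = std.group_matrix(spec.group)

    freqs = aac_vector(ProteinSequence(id=seq_id, residues=residues)).values
    thetas = np.array([theta_tier(residues, d, gvals) for d in range(1, spec.lam + 1)])

    denom = freqs.sum() + spec.omega * thetas.sum()
    first = freqs / denom
    rest = spec.omega * thetas / denom
    names = tuple(f"pse{spec.group}_{r}" for r in RESIDUES) + tuple(
        f"pse{spec.group}_theta{d}" for d in range(1, spec.lam + 1)
    )
    return FeatureVector(names=names, values=np.concatenate([first, rest]))


def build_feature_matrix(
    dataset: InteractionDataset,
    aptamer_spec: KmerSpec | None = None,
    protein_groups: str | list[str] = GROUP_NAMES,
    pseaac_spec: PseAACSpec | None = None,
    table: PropertyTable | None = None,
) -> pd.DataFrame:
    """Encode every pair of a dataset into one wide feature row.

    Columns: aptamer k-mer block, then one PseAAC block per selected group
    in A..H order, then ``label``. The index is ``<aptamer_id>|<protein_id>``.
    With the plain k<=3 aptamer encoder and all eight groups this yields
    84 + 8*50 = 484 feature columns (44 + 400 = 444 for the
    reverse-complement encoder).
    """
    aptamer_spec = aptamer_spec or KmerSpec()
    pseaac_spec = pseaac_spec or PseAACSpec()
    table = table or _default_table()
    groups = [g for g in GROUP_NAMES if g in set(protein_groups)]
    if not groups:
        raise ValueError(f"no valid protein groups in {protein_groups!r}")

    # sequences repeat across pairs; encode each id once
    apt_cache: dict[str, FeatureVector] = {}
    prot_cache: dict[str, list[FeatureVector]] = {}

    rows: list[np.ndarray] = []
    index: list[str] = []
    labels: list[int] = []
    columns: list[str] | None = None
    for apt_id, prot_id, label in dataset.pairs:
        try:
            if apt_id not in apt_cache:
                apt_cache[apt_id] = aptamer_spec.encode(dataset.aptamers[apt_id])
            if prot_id not in prot_cache:
                prot_cache[prot_id] = [
                    pseaac_vector(
                        dataset.proteins[prot_id],
                        PseAACSpec(lam=pseaac_spec.lam, omega=pseaac_spec.omega, group=g),
                        table,
                    )
                    for g in groups
                ]
        except ValueError as exc:
            raise ValueError(f"pair ({apt_id!r}, {prot_id!r}): {exc}") from exc
        apt_vec = apt_cache[apt_id]
        prot_vecs = prot_cache[prot_id]
        if columns is None:
            columns = list(apt_vec.names)
            for fv in prot_vecs:
                columns.extend(fv.names)
        rows.append(np.concatenate([apt_vec.values] + [fv.values for fv in prot_vecs]))
        index.append(f"{apt_id}|{prot_id}")
        labels.append(label)

    frame = pd.DataFrame(rows, index=pd.Index(index, name="pair_id"), columns=columns)
    frame["label"] = labels
    return frame


_TABLE_CACHE: PropertyTable | None = None


def _default_table() -> PropertyTable:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = load_property_table()
    return _TABLE_CACHE


def _residues(seq: ProteinSequence | str) -> tuple[str, str]:
    if isinstance(seq, ProteinSequence):
        return seq.id, seq.residues
    return "<anonymous>", seq
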