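"""Cell-type reference expression profiles and their generation.

A reference holds per-cell-type mean expression profiles for the major
immune populations of whole blood (neutrophils, monocytes, B cells, CD4 T,
CD8 T, NK) together with a map of each cell type to the innate or adaptive
compartment.  Real references (e.g. a sorted-cell RNA-seq compendium) are
read from TSV; synthetic references with designed marker genes are built by
:func:`generate_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DEFAULT_CELL_TYPES = ("neutrophils", "monocytes", "B", "CD4_T", "CD8_T", "NK")

#: myeloid populations form the innate compartment; lymphoid the adaptive
DEFAULT_COMPARTMENTS = {
    "neutrophils": "innate",
    "monocytes": "innate",
    "B": "adaptive",
    "CD4_T": "adaptive",
    "CD8_T": "adaptive",
    "NK": "adaptive",
}


@dataclass
class CellTypeReference:
    """Cell-type x gene mean expression profiles with compartment labels.

    Parameters
    ----------
    profiles
        DataFrame indexed by cell type, columns are gene identifiers,
        values are nonnegative mean expression in arbitrary units.
    compartment_map
        Total map cell type -> {"innate", "adaptive"}.
    marker_assignment
        Optional map gene -> cell type for genes designed (or known) to be
        markers; ``None`` entries or absent genes are shared/background.
    """

    profiles: pd.DataFrame
    compartment_map: dict[str, str]
    marker_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cts = list(self.profiles.index)
        if len(set(cts)) != len(cts):
            raise ValueError("cell types must be unique")
        if (self.profiles.values < 0).any():
            raise ValueError("reference profiles must be nonnegative")
        if not (self.profiles.values.sum(axis=0) > 0).all():
            raise ValueError("every gene needs >=1 nonzero entry")
        missing = set(cts) - set(self.compartment_map)
        if missing:
            raise ValueError(f"compartment_map missing cell types: {sorted(missing)}")
        bad = set(self.compartment_map.values()) - {"innate", "adaptive"}
        if bad:
            raise ValueError(f"unknown compartments: {sorted(bad)}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.columns)

    def compartment(self, cell_type: str) -> str:
        return self.compartment_map[cell_type]

    # -- serialisation ----------------------------------------------------
    def to_tsv(self, profile_path: str | Path, compartment_path: str | Path) -> None:
        self.profiles.to_csv(profile_path, sep="\t")
        with open(compartment_path, "w") as fh:
            yaml.safe_dump(
                {
                    "compartment_map": self.compartment_map,
                    "marker_assignment": self.marker_assignment,
                },
                fh,
            )

    @classmethod
    def from_tsv(
        cls, profile_path: str | Path, compartment_path: str | Path
    ) -> "CellTypeReference":
        profiles = pd.read_csv(profile_path, sep="\t", index_col=0)
        with open(compartment_path) as fh:
            meta = yaml.safe_load(fh)
        return cls(
            profiles=profiles,
            compartment_map=dict(meta["compartment_map"]),
            marker_assignment=dict(meta.get("marker_assignment") or {}),
        )


def generate_reference(
    n_genes: int,
    marker_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    marker_enrichment: float = 20.0,
    base_expression: float = 100.0,
) -> CellTypeReference:
    """Build a synthetic cell-type reference with designed marker genes.

    A fraction ``marker_fraction`` of genes are markers: expressed
    ``marker_enrichment``-fold higher in exactly one cell type (markers are
    split as evenly as possible across cell types).  The remaining genes are
    shared, with mild lognormal variation between cell types.  Marker
    assignments are recorded on the returned reference so recovery tests can
    check marker-set construction against the designed truth.
    """
    if not 0 < marker_fraction < 1:
        raise ValueError("marker_fraction must be in (0, 1)")
    if n_genes < len(cell_types):
        raise ValueError(
            f"n_genes={n_genes} is smaller than the number of cell types "
            f"({len(cell_types)})"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_markers = int(round(n_genes * marker_fraction))
    per_type = np.full(len(cell_types), n_markers // len(cell_types))
    per_type[: n_markers % len(cell_types)] += 1

    # shared baseline: every gene expressed everywhere with mild variation
    base = base_expression * rng.lognormal(0.0, 0.5, size=n_genes)
    profiles = base[None, :] * rng.lognormal(0.0, 0.15, size=(len(cell_types), n_genes))

    marker_assignment: dict[str, str] = {}
    g = 0
    for ct, k in zip(cell_types, per_type):
        for _ in range(int(k)):
            profiles[:, g] = base[g] * rng.lognormal(0.0, 0.1, size=len(cell_types))
            ct_idx = list(cell_types).index(ct)
            profiles[ct_idx, g] *= marker_enrichment
            marker_assignment[genes[g]] = ct
            g += 1

    comp = {ct: DEFAULT_COMPARTMENTS.get(ct, "adaptive") for ct in cell_types}
    return CellTypeReference(
        profiles=pd.DataFrame(profiles, index=list(cell_types), columns=genes),
        compartment_map=comp,
        marker_assignment=marker_assignment,
    )
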