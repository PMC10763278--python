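"""Family definitions: motif patterns, reference alignments, derived spacing.

A family definition couples the family-specific motif with the shared DKTGT
anchor, a reference protein alignment, and the spacing between the motifs.
The spacing is data-derived — the modal residue count strictly between the
motifs over the reference proteins — unless the config pins it explicitly.

The packaged reference alignments are synthetic stand-ins built to the
published family motifs and bait-length range (see ``data/reference/``);
point ``load_family_config`` at your own config to use real family data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .consensus import (
    DEFAULT_FLANK,
    ConsensusQuery,
    ProteinAlignment,
    build_consensus_query,
    read_alignment_fasta,
)
from .motifs import MotifSpec, TwoMotifQuery, derive_spacing, parse_motif_spec

__all__ = ["FamilyDefinition", "load_family_config", "builtin_families", "get_family"]

DEFAULT_ANCHOR = "DKTGT"


@dataclass(frozen=True)
class FamilyDefinition:
    name: str
    upstream: MotifSpec
    downstream: MotifSpec
    alignment: ProteinAlignment | None
    spacing: int
    tolerance: int = 0

    def two_motif_query(self, tolerance: int | None = None) -> TwoMotifQuery:
        return TwoMotifQuery(
            family=self.name,
            upstream=self.upstream,
            downstream=self.downstream,
            spacing=self.spacing,
            tolerance=self.tolerance if tolerance is None else tolerance,
        )

    def consensus_query(
        self, flank: int = DEFAULT_FLANK, exclude_organism: str | None = None
    ) -> ConsensusQuery:
        if self.alignment is None:
            raise ValueError(f"family {self.name!r} has no reference alignment")
        return build_consensus_query(
            self.alignment,
            self.upstream,
            self.downstream,
            flank=flank,
            exclude_organism=exclude_organism,
            family=self.name,
        )


def _load_one(
    name: str, entry: dict, anchor: MotifSpec, base: Path
) -> FamilyDefinition:
    upstream = parse_motif_spec(entry["motif"])
    downstream = parse_motif_spec(entry.get("anchor", anchor.render()))
    alignment = None
    if "reference" in entry:
        alignment = read_alignment_fasta(base / entry["reference"])
    if "spacing" in entry:
        spacing = int(entry["spacing"])
    elif alignment is not None:
        rows = [
            (r.seq_id, r.aligned.replace("-", "")) for r in alignment.records
        ]
        spacing = derive_spacing(rows, upstream, downstream).spacing
    else:
        raise ValueError(
            f"family {name!r}: need either an explicit spacing or a reference"
        )
    return FamilyDefinition(
        name=name,
        upstream=upstream,
        downstream=downstream,
        alignment=alignment,
        spacing=spacing,
        tolerance=int(entry.get("tolerance", 0)),
    )


def load_family_config(path) -> dict[str, FamilyDefinition]:
    """Load family definitions from a YAML config file.

    Schema::

        anchor: DKTGT
        families:
          P3A: {motif: PIA, reference: P3A_reference_synthetic.fasta}
          P4:  {motif: PIS, reference: ..., tolerance: 1}

    Reference alignment paths are resolved relative to the config file.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    anchor = parse_motif_spec(cfg.get("anchor", DEFAULT_ANCHOR))
    base = path.parent
    return {
        name: _load_one(name, entry, anchor, base)
        for name, entry in cfg["families"].items()
    }


_BUILTIN: dict[str, FamilyDefinition] | None = None


def builtin_families() -> dict[str, FamilyDefinition]:
    """The packaged family definitions (synthetic reference data)."""
    global _BUILTIN
    if _BUILTIN is None:
        data_dir = resources.files("twomotif") / "data"
        _BUILTIN = load_family_config(Path(str(data_dir)) / "families.yaml")
    return _BUILTIN


def get_family(name: str, config_path=None) -> FamilyDefinition:
    table = load_family_config(config_path) if config_path else builtin_families()
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; available: {sorted(table)}"
        ) from None
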