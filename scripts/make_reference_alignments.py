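"""Regenerate the packaged SYNTHETIC family reference alignments.

The real reference protein sets behind each family query are not
redistributable, so the package ships synthetic stand-ins: for each family,
six aligned sequences (two per organism tag) built around the published
family motif and the DKTGT anchor at a family-typical spacing, with random
flanks and ~12% point variation outside the motifs.  The P4 set includes a
one-column gap in one organism, mirroring that family's one-residue spacing
variation.

Run from the repository root:  python scripts/make_reference_alignments.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from twomotif.motifs import AA20, parse_motif_spec  # noqa: E402

OUT_DIR = Path(__file__).resolve().parents[1] / "src" / "twomotif" / "data" / "reference"

ORGANISMS = ["Arabidopsis_thaliana", "Oryza_sativa", "Hordeum_vulgare"]
FLANK = 20  # residues outside each motif in the reference window
MUTATION_RATE = 0.12

# family -> (motif pattern, concrete residues per organism, spacing, filename)
FAMILIES = {
    "P1B": ("CPC/SPC", ["CPC", "CPC", "SPC"], 35, "P1B_reference_synthetic.fasta"),
    "P2A/B": ("PEXL", ["PEGL", "PESL", "PEGL"], 38, "P2AB_reference_synthetic.fasta"),
    "P3A": ("PIA", ["PIA", "PIA", "PIA"], 40, "P3A_reference_synthetic.fasta"),
    "P4": ("PIS", ["PIS", "PIS", "PIS"], 43, "P4_reference_synthetic.fasta"),
    "P5": ("PPXXP", ["PPALP", "PPALP", "PPSLP"], 41, "P5_reference_synthetic.fasta"),
}
ANCHOR = "DKTGT"


def random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def mutate(rng: np.random.Generator, base: str, frozen: set[int]) -> str:
    out = list(base)
    for i in range(len(base)):
        if i in frozen or base[i] == "-":
            continue
        if rng.random() < MUTATION_RATE:
            out[i] = rng.choice([a for a in AA20 if a != base[i]])
    return "".join(out)


def build_family(rng: np.random.Generator, name: str) -> list[tuple[str, str, str]]:
    pattern, concrete, spacing, _ = FAMILIES[name]
    upstream = parse_motif_spec(pattern)
    downstream = parse_motif_spec(ANCHOR)
    motif_len = len(concrete[0])
    base_core = random_peptide(rng, FLANK) + "?" * motif_len + \
        random_peptide(rng, spacing) + ANCHOR + random_peptide(rng, FLANK)
    up_span = range(FLANK, FLANK + motif_len)
    down_start = FLANK + motif_len + spacing
    down_span = range(down_start, down_start + len(ANCHOR))
    frozen = set(up_span) | set(down_span)

    records = []
    for org_idx, organism in enumerate(ORGANISMS):
        for copy in (1, 2):
            for _ in range(200):
                row = list(mutate(rng, base_core, frozen))
                row[FLANK : FLANK + motif_len] = list(concrete[org_idx])
                # P4 spacing varies by one residue: give H. vulgare a
                # one-column gap inside the inter-motif stretch
                if name == "P4" and organism == "Hordeum_vulgare":
                    row[FLANK + motif_len + spacing // 2] = "-"
                seq = "".join(row)
                ungapped = seq.replace("-", "")
                if (
                    len(upstream.find_all(ungapped)) == 1
                    and len(downstream.find_all(ungapped)) == 1
                ):
                    break
            else:
                raise RuntimeError(f"could not build a clean row for {name}")
            short = "".join(w[0] for w in organism.split("_"))
            records.append((f"{name.replace('/', '')}_{short}{copy}", organism, seq))
    return records


def main() -> None:
    rng = np.random.default_rng(2024)
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for name, (_, _, _, filename) in FAMILIES.items():
        records = build_family(rng, name)
        path = OUT_DIR / filename
        with open(path, "w") as fh:
            for seq_id, organism, seq in records:
                fh.write(f">{seq_id} organism={organism} synthetic=true\n{seq}\n")
        print(f"wrote {path} ({len(records)} rows, {len(records[0][2])} columns)")


if __name__ == "__main__":
    main()
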