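"""Helpers for taxon labels: clade strings and per-taxon stratum tokens."""

from __future__ import annotations

# Minimal lineage table used to render full rank-prefixed clade strings.
_LINEAGE = {
    "Staphylococcus": "k__Bacteria|p__Firmicutes|c__Bacilli|o__Bacillales|f__Staphylococcaceae",
    "Cutibacterium": "k__Bacteria|p__Actinobacteria|c__Actinobacteria|o__Propionibacteriales|f__Propionibacteriaceae",
    "Corynebacterium": "k__Bacteria|p__Actinobacteria|c__Actinobacteria|o__Corynebacteriales|f__Corynebacteriaceae",
    "Acinetobacter": "k__Bacteria|p__Proteobacteria|c__Gammaproteobacteria|o__Pseudomonadales|f__Moraxellaceae",
    "Micrococcus": "k__Bacteria|p__Actinobacteria|c__Actinobacteria|o__Micrococcales|f__Micrococcaceae",
    "Malassezia": "k__Fungi|p__Basidiomycota|c__Malasseziomycetes|o__Malasseziales|f__Malasseziaceae",
    "Moraxella": "k__Bacteria|p__Proteobacteria|c__Gammaproteobacteria|o__Pseudomonadales|f__Moraxellaceae",
    "Streptococcus": "k__Bacteria|p__Firmicutes|c__Bacilli|o__Lactobacillales|f__Streptococcaceae",
}
_DEFAULT_LINEAGE = ("k__Bacteria|p__Bacteria_unclassified|c__Bacteria_unclassified"
                    "|o__Bacteria_unclassified|f__Bacteria_unclassified")


def clade_string(species: str) -> str:
    """Full rank-prefixed clade string for a ``Genus_species`` label."""
    genus = species.split("_", 1)[0]
    lineage = _LINEAGE.get(genus, _DEFAULT_LINEAGE)
    return f"{lineage}|g__{genus}|s__{species}"


def species_from_clade(clade: str) -> str:
    """Species label (text after ``s__``) from a clade string."""
    last = clade.split("|")[-1]
    return last[3:] if last.startswith("s__") else last


def stratum_token(species: str) -> str:
    """Per-taxon stratum token ``g__Genus.s__Genus_species``."""
    genus = species.split("_", 1)[0]
    return f"g__{genus}.s__{species}"


def species_from_stratum(token: str) -> str:
    """Species label from a stratum token; 'unclassified'/'TOTAL' pass through."""
    if token in ("unclassified", "TOTAL"):
        return token
    for part in token.split("."):
        if part.startswith("s__"):
            return part[3:]
    return token
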