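"""CST-structured synthetic vaginal microbiome compositions.

Generates per-sample taxon relative-abundance vectors that emulate the
five canonical vaginal community state types: CST I dominated by
L. crispatus, CST II by L. gasseri, CST III by L. iners, CST V by
L. jensenii, and CST IV polymicrobial (no dominant taxon, anaerobes
enriched).  Vectors are Dirichlet draws on the simplex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CST_LABELS",
    "ARCHETYPE_TAXON",
    "DEFAULT_TAXA",
    "simulate_composition",
    "simulate_composition_table",
]

CST_LABELS = ("I", "II", "III", "IV", "V")

ARCHETYPE_TAXON = {
    "I": "L. crispatus",
    "II": "L. gasseri",
    "III": "L. iners",
    "V": "L. jensenii",
}

#: Species-level taxa; the four archetype Lactobacillus names always lead.
DEFAULT_TAXA = (
    "L. crispatus",
    "L. gasseri",
    "L. iners",
    "L. jensenii",
    "G. vaginalis",
    "A. vaginae",
    "Prevotella bivia",
    "Megasphaera sp.",
    "Sneathia amnii",
    "Mobiluncus mulieris",
    "Ureaplasma parvum",
    "Streptococcus anginosus",
)

#: Dirichlet concentration for the dominant archetype taxon in CSTs
#: I/II/III/V; chosen so its expected relative abundance is ~0.9 with
#: 12 taxa, comfortably above the 0.7 dominance contract.
_DOMINANT_ALPHA = 40.0
_MINOR_ALPHA = 0.4
#: CST IV: near-uniform over anaerobes plus low-level Lactobacillus, so
#: no taxon's expected abundance exceeds 0.3.
_IV_ANAEROBE_ALPHA = 2.0
_IV_LACTO_ALPHA = 0.5


def _alpha_vector(cst_label: str, taxa: tuple[str, ...]) -> np.ndarray:
    if cst_label not in CST_LABELS:
        raise ValueError(f"unknown CST label {cst_label!r}; expected one of {CST_LABELS}")
    lacto = set(ARCHETYPE_TAXON.values())
    if cst_label == "IV":
        return np.array([
            _IV_LACTO_ALPHA if t in lacto else _IV_ANAEROBE_ALPHA
            for t in taxa])
    dom = ARCHETYPE_TAXON[cst_label]
    return np.array([_DOMINANT_ALPHA if t == dom else _MINOR_ALPHA for t in taxa])


def simulate_composition(
    cst_label: str,
    n_taxa: int = 12,
    seed: int | np.random.Generator | None = None,
) -> pd.Series:
    """Draw one relative-abundance vector for a given CST.

    Returns a Series indexed by taxon name, non-negative and summing
    to 1.  ``n_taxa`` must be >= 5 so all four archetype Lactobacillus
    taxa plus at least one anaerobe are present.
    """
    if n_taxa < 5:
        raise ValueError(f"n_taxa must be >= 5, got {n_taxa}")
    if n_taxa > len(DEFAULT_TAXA):
        taxa = DEFAULT_TAXA + tuple(
            f"taxon_{i}" for i in range(len(DEFAULT_TAXA), n_taxa))
    else:
        taxa = DEFAULT_TAXA[:n_taxa]
    rng = np.random.default_rng(seed)
    vec = rng.dirichlet(_alpha_vector(cst_label, taxa))
    return pd.Series(vec, index=list(taxa), name=cst_label)


def simulate_composition_table(
    cst_labels: list[str],
    n_taxa: int = 12,
    seed: int | np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw a samples-by-taxa relative-abundance table (rows sum to 1)."""
    rng = np.random.default_rng(seed)
    rows = [simulate_composition(lbl, n_taxa, rng) for lbl in cst_labels]
    df = pd.DataFrame(rows)
    df.index = sample_ids if sample_ids is not None else [
        f"S{i:04d}" for i in range(len(cst_labels))]
    return df
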