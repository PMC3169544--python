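"""Published reference data for the tiger swallowtail system.

Small, hand-entered tables from the primary literature on the
*Papilio glaucus* / *P. canadensis* / *P. appalachiensis* hybrid-species
complex, used for worked examples and for recomputing the published
summary arithmetic:

* per-gene counts of polymorphisms/haplotypes and their species-specific
  subsets for the seven sequenced genes (mtDNA *COI* plus six Z-linked
  genes);
* the mtDNA clock calibration inputs (divergence to *P. multicaudata*
  and the per-lineage *COI* rate);
* field counts of suspected *glaucus* × *appalachiensis* hybrids;
* binary ecological/morphological trait states for the clade, and the
  backbone species topology used for trait mapping (the hybrid species
  is attached post hoc, never inside the parsimony pass).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "diversity_counts",
    "COI_DIVERGENCE_PERCENT",
    "COI_RATE_PERCENT_PER_LINEAGE_PER_MYR",
    "N_SUSPECTED_HYBRIDS",
    "N_PHENOTYPICALLY_PURE",
    "species_traits",
    "backbone_newick",
]

# Per-gene diversity counts: (polymorphisms, species-specific polymorphisms,
# haplotypes, species-specific haplotypes) for each focal species.
_DIVERSITY = {
    ("COI", "canadensis"): (11, 7, 11, 10),
    ("COI", "glaucus"): (18, 10, 19, 15),
    ("COI", "appalachiensis"): (8, 3, 7, 4),
    ("KET", "canadensis"): (37, 25, 21, 17),
    ("KET", "glaucus"): (20, 18, 15, 13),
    ("KET", "appalachiensis"): (30, 15, 11, 8),
    ("TH", "canadensis"): (6, 4, 8, 2),
    ("TH", "glaucus"): (24, 14, 27, 25),
    ("TH", "appalachiensis"): (23, 8, 19, 12),
    ("TPI", "canadensis"): (57, 53, 20, 17),
    ("TPI", "glaucus"): (19, 9, 22, 20),
    ("TPI", "appalachiensis"): (21, 9, 10, 7),
    ("PER", "canadensis"): (8, 2, 10, 4),
    ("PER", "glaucus"): (5, 3, 30, 27),
    ("PER", "appalachiensis"): (21, 16, 9, 5),
    ("LDH", "canadensis"): (46, 19, 26, 23),
    ("LDH", "glaucus"): (38, 23, 28, 27),
    ("LDH", "appalachiensis"): (49, 15, 14, 11),
    ("PAH", "canadensis"): (46, 21, 26, 23),
    ("PAH", "glaucus"): (109, 43, 24, 23),
    ("PAH", "appalachiensis"): (100, 14, 15, 12),
}


def diversity_counts() -> pd.DataFrame:
    """Published per-gene diversity counts with exact proportions."""
    rows = []
    for (gene, sp), (np_, nsp, nh, nsh) in _DIVERSITY.items():
        rows.append(
            {
                "gene": gene,
                "species": sp,
                "n_polymorphisms": np_,
                "n_species_specific_polymorphisms": nsp,
                "n_haplotypes": nh,
                "n_species_specific_haplotypes": nsh,
                "proportion_specific_polys": nsp / np_,
                "proportion_specific_haps": nsh / nh,
            }
        )
    return pd.DataFrame(rows)


# mtDNA clock calibration: mean COI divergence (%) between P. multicaudata and
# the three focal species, and the per-lineage COI divergence rate.
COI_DIVERGENCE_PERCENT = 3.17
COI_RATE_PERCENT_PER_LINEAGE_PER_MYR = 1.15

# Field counts within the glaucus/appalachiensis overlap zone.
N_SUSPECTED_HYBRIDS = 16
N_PHENOTYPICALLY_PURE = 114 + 172  # pure appalachiensis + pure glaucus


def species_traits() -> pd.DataFrame:
    """Binary ecological/morphological trait states for the clade.

    1 = present, 0 = absent.  Traits: Batesian mimicry (melanic mimetic
    female form), the Z-linked mimicry enabler allele, the yellow
    (ancestral) female form, female dimorphism, obligatory pupal
    diapause, and univoltinism.  Obligatory diapause and univoltinism
    are unique to *canadensis* among the non-hybrid taxa; mimicry and
    the enabler occur in *garcia* and *glaucus*.  The hybrid species
    *appalachiensis* combines *glaucus*-type mimicry traits with
    *canadensis*-type thermal traits and is excluded from parsimony
    passes (attach it post hoc).
    """
    cols = ["mimicry", "enabler", "yellow_form", "female_dimorphism", "diapause", "univoltinism"]
    data = {
        "garamas": [0, 0, 1, 0, 0, 0],
        "multicaudata": [0, 0, 1, 0, 0, 0],
        "rutulus": [0, 0, 1, 0, 0, 0],
        "eurymedon": [0, 0, 1, 0, 0, 0],
        "alexiares": [0, 0, 1, 0, 0, 0],
        "garcia": [1, 1, 0, 0, 0, 0],
        "glaucus": [1, 1, 1, 1, 0, 0],
        "canadensis": [0, 0, 1, 0, 1, 1],
        "appalachiensis": [1, 1, 1, 1, 1, 1],
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def backbone_newick() -> str:
    """Species backbone topology (outgroup *garamas*), hybrid excluded."""
    return (
        "((multicaudata:1,((rutulus:1,eurymedon:1):1,"
        "((alexiares:1,garcia:1):1,(glaucus:1,canadensis:1):1):1):1):1,garamas:1);"
    )
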