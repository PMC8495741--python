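"""Packaged reference data.

Small, fixed inputs that the analyses are exercised against:

* an 18-species budding-yeast tree used as the master topology for
  rate-covariation simulations (topology follows the accepted
  Saccharomycetaceae / CTG-clade relationships; branch lengths are fixed,
  plausible amino-acid substitution distances, not estimates from data);
* published ``lys2::insE-A14`` reversion-rate measurements for MLH3/PMS1
  functional assays, used as worked examples for relative-rate reporting;
* reference tetratype fractions for the CEN8-THR1 spore-autonomous
  crossover assay (wild type vs. mlh3 null);
* domain boundaries of S. cerevisiae Mlh3 and Pms1 (1-based, ungapped
  residue coordinates).
"""

from __future__ import annotations

# Unrooted (basal trifurcation) 18-taxon tree: post-WGD Saccharomycetaceae,
# Lachancea/Kluyveromyces/Eremothecium, and the CTG clade.
MASTER_TREE_NEWICK = (
    "(((((Saccharomyces_cerevisiae:0.05,Saccharomyces_paradoxus:0.06):0.04,"
    "Saccharomyces_mikatae:0.08):0.03,Saccharomyces_bayanus:0.10):0.09,"
    "((Candida_glabrata:0.22,Naumovozyma_castellii:0.20):0.05,"
    "Vanderwaltozyma_polysporus:0.19):0.04):0.08,"
    "((Lachancea_kluyveri:0.15,(Lachancea_thermotolerans:0.11,"
    "Lachancea_waltii:0.12):0.05):0.07,(Kluyveromyces_lactis:0.18,"
    "Eremothecium_gossypii:0.21):0.06):0.10,"
    "(((Candida_albicans:0.08,Candida_dubliniensis:0.07):0.06,"
    "Candida_tropicalis:0.12):0.08,((Candida_lusitaniae:0.17,"
    "Candida_guilliermondii:0.18):0.04,Debaryomyces_hansenii:0.16):0.05):0.25);"
)

#: Published lys2::insE-A14 reversion rates (method-of-the-median estimates)
#: for strains assayed alongside a wild-type reference, with the relative
#: rate each source reports.  ``rate`` is in units of ``scale`` mutations
#: per cell per generation; ``n`` is the number of independent cultures.
#: ``reported_relative`` is the published rate ratio versus the reference
#: strain of the same panel (the first row of each panel, relative rate 1);
#: ``precision`` is one unit in the last printed digit of that ratio.
REVERSION_REFERENCE = {
    "sk1_integrated": {
        "description": "mlh3 alleles integrated at the MLH3 locus (SK1)",
        "scale": 1e-6,
        "reference_strain": "MLH3",
        "strains": [
            {"strain": "MLH3", "rate": 1.03, "n": 42,
             "ci": (0.81, 1.39), "reported_relative": 1.0,
             "precision": 0.01},
            {"strain": "mlh3-null", "rate": 6.24, "n": 39,
             "ci": (4.53, 8.51), "reported_relative": 6.05,
             "precision": 0.01},
            {"strain": "PPP-chimera", "rate": 8.29, "n": 15,
             "ci": (2.85, 22.2), "reported_relative": 8.1,
             "precision": 0.1},
            {"strain": "PMM-chimera", "rate": 15.6, "n": 15,
             "ci": (3.29, 29.0), "reported_relative": 15.1,
             "precision": 0.1},
            {"strain": "mlh3-Block1", "rate": 2.26, "n": 15,
             "ci": (1.18, 3.78), "reported_relative": 2.20,
             "precision": 0.01},
            {"strain": "mlh3-PIP2", "rate": 0.567, "n": 15,
             "ci": (0.41, 0.75), "reported_relative": 0.55,
             "precision": 0.01},
        ],
    },
    "s288c_pms1_null": {
        "description": "plasmid-borne alleles in a pms1-null background (S288c)",
        "scale": 1e-7,
        "reference_strain": "PMS1-ARS-CEN",
        "strains": [
            {"strain": "PMS1-ARS-CEN", "rate": 2.99, "n": 30,
             "ci": (2.11, 3.85), "reported_relative": 1.0,
             "precision": 0.01},
            {"strain": "PMS1-2mu", "rate": 22.4, "n": 18,
             "ci": (15.1, 63.5), "reported_relative": 7.50,
             "precision": 0.01},
            {"strain": "empty-ARS-CEN", "rate": 20300, "n": 29,
             "ci": (12900, 28700), "reported_relative": 6800,
             "precision": 100.0},
            {"strain": "empty-2mu", "rate": 18900, "n": 18,
             "ci": (15900, 21300), "reported_relative": 6320,
             "precision": 10.0},
        ],
    },
}

#: Reference single-crossover (tetratype) fractions in the CEN8-THR1
#: interval: (percent tetratype, tetrads scored).
TETRATYPE_REFERENCE = {
    "wild_type": (37.1, 1023),
    "mlh3_null": (18.3, 1239),
}

#: 1-based inclusive residue spans of the three structural domains.
DOMAIN_BOUNDARIES = {
    "Mlh3": {"atp_binding": (1, 375), "linker": (376, 488),
             "endonuclease": (489, 715)},
    "Pms1": {"atp_binding": (1, 361), "linker": (362, 638),
             "endonuclease": (639, 877)},
}
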