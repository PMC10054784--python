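"""Published reference facts for alasmontamine A used by tests and examples.

Only values printed in the primary literature are recorded here: the
molecular formula, the carbon-type inventory, the stereocenter count, and
the outcome of the staged center selection (six principle centers, one
NOESY exclusion, three energy exclusions). Full shift tables are not
publicly reproduced, so pipeline runs use the synthetic generator.
"""

FORMULA = "C84H91N8O12"

#: (element, hybridization, carbon_class) -> count; sums to 84 carbons
CARBON_CLASS_COUNTS = {
    ("C", "sp2", "quaternary"): 18,
    ("C", "sp3", "quaternary"): 12,
    ("C", "sp2", "methine"): 15,
    ("C", "sp3", "methine"): 10,
    ("C", "sp3", "methylene"): 27,
    ("C", "sp3", "methyl"): 2,
}

N_STEREOCENTERS = 22

#: the six centers varied combinatorially (2^6 = 64 candidates)
PRINCIPLE_CENTERS = ("C-15′", "C-15‴", "C-15″", "C-21‴", "C-16′", "C-21′")

#: excluded from the principle set by a missing NOESY correlation
NOESY_EXCLUDED = ("C-20‴",)

#: excluded because the flipped diastereomer lies ≥ 30 kcal/mol above the base
ENERGY_EXCLUDED = ("C-21″", "C-20′", "C-20")
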