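"""Frozen published reference values for the 3-node pattern catalog.

Used as regression fixtures by the unit and acceptance tests.  Energy
cells are printed at 2 decimals; three cells are known to be off by one
unit in the last printed digit relative to full-precision recomputation
(LQt of id 38, LQt of id 102, AQt of id 110), so table-wide comparisons
use a one-ULP tolerance of 0.0105 while spot checks use 0.005.
"""

# id -> (E, LE, QE, AAt, LLt, QQt, ALt, AQt, LQt)
ENERGY_TABLE_3 = {
    6: (0.00, 2.67, 2.67, 1.41, 4.32, 4.32, 1.41, 1.41, 3.83),
    12: (0.00, 2.67, 2.67, 2.00, 4.34, 4.34, 2.00, 2.00, 3.93),
    14: (2.00, 4.00, 4.00, 2.41, 6.13, 6.13, 3.00, 3.00, 5.45),
    36: (0.00, 2.67, 2.67, 1.41, 4.32, 4.32, 1.41, 1.41, 3.83),
    38: (0.00, 4.00, 4.00, 2.24, 6.39, 6.34, 2.63, 2.37, 6.01),
    46: (2.00, 5.33, 5.33, 2.73, 8.24, 8.16, 2.00, 3.86, 7.59),
    74: (2.00, 4.00, 4.00, 2.41, 6.13, 6.13, 3.00, 3.00, 5.45),
    78: (2.83, 5.33, 5.33, 2.83, 8.00, 8.00, 3.86, 3.86, 7.29),
    98: (3.00, 4.29, 4.46, 3.00, 6.29, 6.46, 4.25, 4.36, 6.01),
    102: (3.06, 5.33, 5.56, 3.24, 8.17, 8.25, 4.76, 5.02, 7.57),
    108: (2.00, 5.33, 5.33, 2.73, 8.24, 8.16, 2.00, 3.86, 7.59),
    110: (3.24, 6.67, 6.72, 3.49, 10.09, 10.09, 5.38, 5.70, 9.40),
    238: (4.00, 8.00, 8.00, 4.00, 12.00, 12.00, 6.47, 6.93, 11.21),
}

ONE_ULP = 0.0105  # one unit in the last printed decimal, plus rounding slack
SPOT = 0.005  # half a unit: exact agreement at printed precision

#: correlation reciprocity r per pattern
RECIPROCITY_R_3 = {
    6: -0.5, 12: -0.5, 14: 1 / 3, 36: -0.5, 38: -1.0, 46: -0.5, 74: 1 / 3,
    78: 1.0, 98: -1.0, 102: -0.5, 108: -0.5, 110: -0.2, 238: 1.0,
}

#: traditional reciprocity R = L↔/L under its stated definition.  The
#: published table prints 0 for ids 14, 46, 74, 102, 108 and 110 even
#: though each contains a mutual dyad; the definitional values below
#: are what L↔/L actually gives (the r > 0 of ids 14/74 confirms the
#: bidirectional links are real).
RECIPROCITY_R_TRADITIONAL_3 = {
    6: 0.0, 12: 0.0, 14: 2 / 3, 36: 0.0, 38: 0.0, 46: 1 / 2, 74: 2 / 3,
    78: 1.0, 98: 0.0, 102: 1 / 2, 108: 1 / 2, 110: 4 / 5, 238: 1.0,
}

#: ids whose printed R (0) disagrees with the stated definition
RECIPROCITY_DISCREPANT_IDS = {14, 46, 74, 102, 108, 110}

#: edge counts per pattern
EDGES_3 = {
    6: 2, 12: 2, 14: 3, 36: 2, 38: 3, 46: 4, 74: 3, 78: 4, 98: 3,
    102: 4, 108: 4, 110: 5, 238: 6,
}

#: cyclomatic complexity CC = e − N + 2P
CC_3 = {
    6: 3, 12: 1, 14: 2, 36: 1, 38: 2, 46: 3, 74: 0, 78: 1, 98: 0,
    102: 1, 108: 1, 110: 2, 238: 3,
}

#: printed ascending competition ranks (id order as above)
CC_RANKS_3 = [11, 3, 8, 3, 8, 11, 1, 3, 1, 3, 3, 8, 11]
KC_RANKS_3 = [1, 3, 6, 2, 8, 13, 4, 9, 7, 10, 11, 12, 5]

#: id order used by the rank vectors
ID_ORDER_3 = [6, 12, 14, 36, 38, 46, 74, 78, 98, 102, 108, 110, 238]

#: Case A distinguishability class counts verified against the energy table
CASE_A_CLASSES_3 = {"E": 7, "LE": 6, "AAt": 10}

IRREDUCIBLE_3 = {6, 12, 36}
IRREDUCIBLE_4 = {14, 28, 74, 76, 280, 328, 392, 2184}
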