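"""Compute H-scores from cell tallies and area fractions.

The H-score weights the percentage of cells (or area) at each staining
intensity by its grade: 3*%strong + 2*%moderate + 1*%weak, giving 0-300.
"""

from ihcdx.hscore import CellTally, IntensityFractions, hscore_from_fractions, hscore_from_tally

# A pathologist counted 1,000 cells: 100 unstained, 400 weak, 300 moderate,
# 200 strong.
tally = CellTally((100, 400, 300, 200))
print(f"tally H-score: {hscore_from_tally(tally):.1f}")  # 160.0

# The same composition expressed as area fractions from image analysis.
fractions = IntensityFractions((0.10, 0.40, 0.30, 0.20))
print(f"fraction H-score: {hscore_from_fractions(fractions):.1f}")  # identical

# "mild" is accepted as a synonym for the moderate class.
alias = CellTally.from_mapping({"none": 25, "weak": 25, "mild": 25, "strong": 25})
print(f"uniform mix: {hscore_from_tally(alias):.1f}")  # 150.0 (scale midpoint)
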