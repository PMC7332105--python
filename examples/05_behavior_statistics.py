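"""Behavioral and mosaic statistics from printed counts.

The supporting statistics run directly from published summary numbers:
optomotor plate counts (Fisher exact), chimeric-retina cone counts per
section (summary t test), and optokinetic eye-movement counts
(tie-aware exact Mann-Whitney U).
"""
import conespect as cs
from conespect.behavior import ContingencyTable2x2, GroupSummary

# Optomotor response: larvae swim with a drifting grating and pool at the
# plate rim (region 3).  Wild types respond to white/black gratings; the
# red-blind frameshift mutant ignores red/black gratings.
wt_white = ContingencyTable2x2(33, 3, 14, 22)
mut_red = ContingencyTable2x2(44, 2, 43, 3)
print(f"OMR wild type, white/black: p = {cs.fisher_exact_2x2(wt_white):.2g}")
print(f"OMR mutant,    red/black:   p = {cs.fisher_exact_2x2(mut_red):.2g}")

# Chimeric retina: green cones per 45x45 um section rise where red cones
# are missing (mean +/- SE over five sections per region).
res = cs.summary_t_test(GroupSummary(72.60, 3.53, 5), GroupSummary(91.20, 2.20, 5))
print(f"\ngreen cones, wild-type vs mutant region: "
      f"t = {res.t:.2f}, df = {res.df}, p = {res.p:.4f}")

# Optokinetic response: correct eye movements per minute are small tied
# integers, so the exact tie-aware null distribution matters.
wt_okr = [0, 1, 1, 2, 2, 3, 3, 4, 1, 2]
mut_okr = [0, 0, 0, 1, 0, 0, 1, 0, 0, 0]
mwu = cs.mann_whitney_u(wt_okr, mut_okr)
print(f"\nOKR eye movements, wt vs mut: U = {mwu.U:g}, p = {mwu.p:.4f} ({mwu.method})")
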