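"""Treatment-group comparison: the additive effect of pressure and MGF.

Runs a 200-replicate SSA ensemble per condition and tabulates the
12-24 h window mean of Scleraxis and the active kinases, as fold change
versus the untreated control.
"""

from mechanoscx import compare_conditions, default_parameters

params = default_parameters()
table = compare_conditions(params, n_reps=200, t_end=48.0, seed=1,
                           mode="ssa")

cols = ["condition", "fold_SCX", "fold_FAK_a", "fold_FYN_a", "fold_ERK_a",
        "fold_P38_a"]
print(table.table[cols].round(3).to_string(index=False))

tc = table.scx_summaries["pressure+MGF"]
print(f"\npressure+MGF Scleraxis: peak {tc.peak_value:.0f} copies at "
      f"{tc.peak_time:.1f} h, back within 10% of baseline at "
      f"{tc.return_time:.1f} h")

# Each stimulus alone raises Scleraxis; the combination exceeds either
# single treatment (fold_SCX ordering), while MGF alone leaves FAK
# essentially at control (fold_FAK_a close to 1) because MGF signals
# through Fyn/ERK, not through the pressure-gated integrin/FAK step.
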