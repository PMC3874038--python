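"""Cross-species ranked-list overlap with a Monte-Carlo null band.

Simulates linked mouse and human studies (40% of mouse disease genes have
sign-concordant human DE orthologs), translates the human DEGs into mouse
identifiers, and asks how many of the top-k most up-regulated mouse genes
fall into that translated set, compared with random ordering.
"""

import transconcord as tc

config = tc.SimulationConfig(n_genes=2000)
bundle = tc.generate_all(config, seed=2)

mouse = tc.filter_expressed(bundle["mouse_study"])
mtab = tc.fit_differential(mouse, "disease", "naive")
human = tc.filter_expressed(bundle["human_study"])
htab = tc.fit_differential(human, "LS", "NL")
hdegs = tc.call_degs(htab)
hsig = tc.GeneSignature("human_LS_vs_NL", hdegs.up, hdegs.down, "human")

# ortholog map is mouse -> human; reverse it to translate human -> mouse
translated = tc.translate_signature(
    hsig, bundle["ortholog_map"].reversed(), target_species="mouse"
)
print(f"human DEGs: {len(hdegs.up)} up / {len(hdegs.down)} down; "
      f"translated to mouse: {len(translated.up)} up / {len(translated.down)} down")

venn = tc.venn_fraction(tc.call_degs(mtab), translated)
print(f"{venn.fraction:.1%} of mouse DEGs are present in the translated human "
      f"signature ({venn.n_intersection}/{venn.n_deg})")

universe = set(mtab.index)
up, _ = tc.ranked_top_lists(mtab, K=500)
curve = tc.concordance_curve(
    up, set(translated.up) & universe, universe, K=500, n_reps=2000, seed=2
)
print("\n  k  observed  null_mean  95% null band")
for k in (50, 100, 250, 500):
    i = k - 1
    print(f"{k:>4}  {curve.observed[i]:>7}  {curve.null_mean[i]:>9.1f}  "
          f"[{curve.null_lo[i]:.0f}, {curve.null_hi[i]:.0f}]")
# observed counts far above the null band indicate the mouse model's
# strongest up-regulated genes are enriched for human disease orthologs.
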