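"""In-silico compound vulnerability screen on a simulated sensitivity table.

Simulates a PRISM-style screen (200 cell lines x 500 compounds, 5 planted
hits whose AUC anti-correlates with a biomarker's expression at |r| ~ 0.8),
correlates biomarker expression with every compound's AUC, adjusts with
Benjamini-Hochberg, and ranks the FDR-passing sensitive compounds.
"""

from ithkit import generate_drug_screen, rank_hits, screen_all, stratify_by_quantile

expression, auc_table, planted = generate_drug_screen(
    n_lines=200, n_compounds=500, n_hits=5, effect=0.8, seed=0
)
results = screen_all(expression, auc_table, min_lines=20)

print("10 most negative expression-AUC correlations:")
print(results.head(10).round(4).to_string(index=False))
hits = rank_hits(results, direction="sensitive", q_max=0.05)
print(f"\nplanted hits: {sorted(planted)}")
print(f"recovered in top 10: {sorted(set(planted) & set(results.head(10)['compound_id']))}")
print(f"BH-significant sensitive compounds (q <= 0.05): {len(hits)}")

# the top/bottom 20% stratification used for biomarker-high vs -low groups
groups = stratify_by_quantile(expression, q=0.2)
print(f"\nbiomarker-high lines: {(groups == 'high').sum()}, "
      f"low: {(groups == 'low').sum()}, excluded: {(groups == 'excluded').sum()}")
# negative r means lower AUC (greater sensitivity) in biomarker-high lines;
# all planted hits should sit at the top with q far below 0.05
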