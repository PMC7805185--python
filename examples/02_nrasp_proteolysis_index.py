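"""Quantify proteolysis with the NRASP index and detect a perturbed group.

NRASP (normalized relative abundance of semi-tryptic peptides) divides a
group's semi-tryptic relative abundance by its fully tryptic relative
abundance; 1 means proteolysis proportional to abundance.  Here the CD
sample group carries a 2x proteolysis rate for the genus Prevotella, and
Kruskal-Wallis + Dunn-Bonferroni testing recovers it.
"""

import semipep as sp

cfg = sp.SimConfig(seed=0, group_multipliers={"CD": {"Prevotella": 2.0}})
bundle = sp.simulate_dataset(cfg)
res = sp.run_stages(bundle.engines, bundle.db, bundle.tree, bundle.pep2taxa,
                    bundle.go_map, bundle.ec_map, bundle.metadata,
                    sp.PipelineParams(seed=0))

nrasp = res.nrasp_filtered
for genus in ("Prevotella", "Bacteroides", "Roseburia", "Faecalibacterium"):
    row = nrasp.loc[f"taxon:{genus}"]
    per_group = {g: row[[c for c in nrasp.columns if c.startswith(g)]].median()
                 for g in ("Ctrl", "CD", "UC")}
    print(f"{genus:18s} median NRASP  "
          + "  ".join(f"{g}={v:.2f}" for g, v in per_group.items()))

print()
for t in res.nrasp_tests:
    if t.feature != "taxon:Prevotella":
        continue
    print(f"Kruskal-Wallis for {t.feature}: H={t.h_statistic:.1f}, "
          f"p={t.p_kw:.2e}")
    for pw in t.pairwise:
        flag = " *" if pw.p_adj < 0.05 else ""
        print(f"  Dunn {pw.pair[0]} vs {pw.pair[1]}: z={pw.z:+.2f}, "
              f"adjusted p={pw.p_adj:.2e}{flag}")
print("\nThe boosted genus shows elevated NRASP in CD only; the adjusted "
      "p below 0.05 for CD vs Ctrl flags the proteolysis change.")
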