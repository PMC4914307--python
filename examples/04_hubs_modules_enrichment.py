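"""Hub selection, MCODE module mining, and hypergeometric enrichment of a
disease gene set in the hubs of an inferred ceRNA network."""

import cernanet as cn

mset, mrna_catalog, lncrna_catalog, truth = cn.generate_cohort(
    cn.SyntheticSpec(seed=5)
)
result = cn.infer_network(
    mset, mrna_catalog, lncrna_catalog, cn.InferenceOptions(cerna_edges=True)
)
net = result["network"]

hubs = cn.identify_hubs(net, fraction=0.25)
print(f"hub counts (top 25% by degree, per class): {hubs.counts()}")

modules = cn.mcode_modules(net)
print(f"MCODE found {len(modules)} dense modules; top module: "
      f"{sorted(modules[0].members)} (score {modules[0].score:.2f})")

(disease_set,) = cn.planted_gene_sets(truth)
universe = (
    set(mset.mirna.molecule_ids)
    | set(mset.lncrna.molecule_ids)
    | set(mset.mrna.molecule_ids)
)
enr = cn.hypergeometric_enrichment(hubs.all_hubs(), disease_set, universe)
print(f"disease-set enrichment in hubs: overlap {enr.overlap}/{enr.selection_size}, "
      f"p = {enr.p_value:.3g}, fold = {enr.fold_enrichment:.1f}")
print("a small p says the hubs over-represent the disease genes relative to "
      "drawing the same number of molecules at random from the universe")

lnc = sorted(truth.planted_pairs)[0][0]
inferred = cn.neighbor_function_inference(net, lnc, [disease_set], universe)
print(f"guilt-by-association for {lnc}: top annotation "
      f"'{inferred[0].set_name}' (p = {inferred[0].p_value:.3g})")
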