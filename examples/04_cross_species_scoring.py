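"""Score a dataset whose gene identifiers come from another namespace.

A renamed copy of the query panel stands in for an ortholog-labelled
(e.g. human) dataset; a one-to-one mapping table translates its ids back
to the signature's namespace before scoring. Scores after mapping are
identical to scoring the original data directly.
"""

import nohelp as nh

matrix, meta, _ = nh.simulate_reference(nh.SimulationConfig(seed=17))
signature = nh.derive_signature(matrix, meta)
expr = nh.cpm(nh.remove_zero_genes(matrix))
centroids = nh.compute_centroids(expr, meta, signature)

panel = nh.simulate_query(centroids, w=0.75, noise_sd=0.1, n_samples=3,
                          seed=42)
renamed, mapping = nh.rename_species(panel, prefix="HS_")
print(f"renamed panel gene ids look like: {renamed.gene_ids[0]}")
print(f"mapping holds {len(mapping)} one-to-one pairs")

for s in renamed.sample_ids:
    translated = nh.map_profile(renamed.profile(s), mapping)
    r = nh.no_help_score(translated, centroids, sample_id=s)
    direct = nh.no_help_score(panel.profile(s), centroids, sample_id=s)
    print(f"  {s}: mapped score {r.no_help_score:+.4f} "
          f"== direct score {direct.no_help_score:+.4f} "
          f"({r.n_genes_used} genes)")
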