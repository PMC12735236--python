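"""Chemotype recovery from the printed relative-content matrix.

Runs the fixed normalization chain (sum-normalize, log10, auto-scale)
over the 16-compound x 9-specimen matrix, then PCA and Ward clustering.
"""

from isomet import hcluster, normalize_table, pca, table3_fixture

table = table3_fixture()
norm = normalize_table(table)
print(f"matrix: {table.n_features} compounds x {table.n_samples} specimens")

res = pca(norm, n_components=2)
print(f"PC1 {res.explained_pct[0]:.1f}% / PC2 {res.explained_pct[1]:.1f}% of variance")
for sample, score in zip(res.samples, res.scores):
    print(f"  {sample:15s} PC1 {score[0]:+6.2f}  PC2 {score[1]:+6.2f}")

labels = hcluster(norm).cut(2)
groups = {}
for s, l in labels.items():
    groups.setdefault(l, []).append(s)
for l, members in sorted(groups.items()):
    print(f"cluster {l}: {', '.join(members)}")

# The three Phan Thiet specimens (PIBOC O66-###) separate from the six
# site-1-3 specimens on PC1 and form their own cluster at k = 2 -- the
# two chemotypes of the sponge population.
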