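"""Phylogenetically corrected correlation of ZNF and retroelement counts.

Simulates two traits evolving by correlated Brownian motion (rho = 0.8) on
a 150-taxon Yule tree, then compares the naive cross-species Spearman
correlation with the correlation of Felsenstein's independent contrasts.
"""

from zfte.phylo import correlate_traits
from zfte.sim import simulate_trait_tree

tree, traits = simulate_trait_tree(n_taxa=150, rho=0.8, seed=7)
log_znf = {sp: v[0] for sp, v in traits.items()}
log_retro = {sp: v[1] for sp, v in traits.items()}

raw, n_raw = correlate_traits(log_znf, log_retro, method="raw", log_transform=False)
pic, n_pic = correlate_traits(
    log_znf, log_retro, tree, method="pic", log_transform=False
)
signed, _ = correlate_traits(
    log_znf, log_retro, tree, method="pic", positivize=False, log_transform=False
)

print(f"raw Spearman rho        = {raw.statistic:+.3f}  (p={raw.p:.2e}, n={n_raw})")
print(f"PIC rho (positivized)   = {pic.statistic:+.3f}  (p={pic.p:.2e}, n={n_pic})")
print(f"PIC rho (signed)        = {signed.statistic:+.3f}")
# The signed-contrast rho estimates the simulated correlation (Spearman of a
# rho=0.8 bivariate normal is ~0.79); the positivized version is the
# orientation-invariant test statistic and is attenuated by folding.
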