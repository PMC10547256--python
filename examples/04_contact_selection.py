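"""Detect positive selection concentrated at DNA-contacting finger residues.

Simulates a codon alignment of a 10-finger ZNF across 12 paralogs where the
-1/+2/+3/+6 contact positions evolve with omega = 5 and everything else with
omega = 0.2, then tests contact-residue enrichment for omega > 1.
"""

import numpy as np

from zfte.selection import (
    contact_enrichment,
    contact_site_indices,
    site_omega_profile,
)
from zfte.sim import simulate_codon_alignment, simulate_trait_tree
from zfte.sim.genome import _random_quads, znf_protein

rng = np.random.default_rng(0)
protein = znf_protein(rng, _random_quads(rng, 10))
contact = contact_site_indices(protein)
omegas = [5.0 if i in contact else 0.2 for i in range(len(protein))]

tree, _ = simulate_trait_tree(12, rho=0.0, seed=0)
for edge in tree.preorder_edge_iter():
    if edge.length:
        edge.length *= 0.3  # ~0.3 substitutions per codon site per unit depth

alignment, _ = simulate_codon_alignment(tree, omegas, kappa=2.0, seed=0)
profile = site_omega_profile(alignment, contact_sites=contact)
odds_ratio, p = contact_enrichment(profile)

defined = [s for s in profile if np.isfinite(s.omega)]
hi = np.mean([s.omega for s in defined if s.is_contact])
lo = np.mean([s.omega for s in defined if not s.is_contact])
print(f"protein length:          {len(protein)} aa, {len(contact)} contact sites")
print(f"mean omega (contact):    {hi:.2f}")
print(f"mean omega (other):      {lo:.2f}")
print(f"Fisher enrichment:       OR = {odds_ratio:.1f}, p = {p:.2e}")
# An odds ratio far above 1 says sites with dN/dS > 1 are concentrated at
# the base-contacting positions, the signature of an evolutionary arms race.
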