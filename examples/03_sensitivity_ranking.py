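"""Rank species fragility by SVD of time-averaged kinetic sensitivities.

Sensitivities dx_i/dk_j are integrated alongside the states, scaled to
dimensionless log-sensitivities, time-averaged over the response, and
decomposed by SVD; a species' score is the fraction of the leading singular
vectors in which it carries weight.  Comparing ±insulin shows control
shifting onto the receptor/PI3K axis when the hormone is present.
"""

from insulinit.sensitivity import ensemble_species_scores
from insulinit.synthetic import build_toy_insulin_network, toy_conditions

net = build_toy_insulin_network()
conds = toy_conditions()
members = [net.nominal_parameters()]

scores = {}
for name in ("basal", "insulin"):
    df = ensemble_species_scores(
        net, members, conds[name], window=(0, 100), threshold=0.1
    )
    scores[name] = df.set_index("species")["score"]

print(f"{'species':10s} {'basal':>7s} {'insulin':>9s}")
for sid in ("Ins", "IRa", "PI3Ka", "PIP3", "PTEN", "RhebGTP", "mTORC1a", "R80S"):
    print(f"{sid:10s} {scores['basal'][sid]:7.2f} {scores['insulin'][sid]:9.2f}")
print("higher score = more fragile (trajectories respond strongly to "
      "parameter perturbations); receptor-module scores rise from ~0 only "
      "when insulin is present")
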