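"""Downstream harms: each modelled component beside its ledger row.

The consumption shift drives NNP-based psychosis/schizophrenia cases, CUD
treatment demand, road-accident burden, education-attainment income loss
and the criminal-record components; each model output is shown against the
(main, low, high) of its packaged ledger row.
"""

from cannabis_cba import consumption_shift, default_config, modelled_components
from cannabis_cba.harms import (
    accident_burden,
    attributable_case_burden,
    cud_eligible_users,
    delta_users_by_stratum,
)

config = default_config()
shift = consumption_shift(config)
params = config.harm_parameters()

burden = attributable_case_burden(delta_users_by_stratum(shift.baseline, shift.shifted), params)
print("additional incident cases under legalisation:")
for condition, b in burden.items():
    print(f"  {condition:<14} {b.cases:5.1f} cases  ({b.cost_millions:.2f} m)")

eligible_sq, eligible_lr = cud_eligible_users(shift.baseline, shift.shifted, params.cud_first_year_factor)
print(f"CUD treated-number ratio: {eligible_lr / eligible_sq:.2f}")

base = accident_burden(shift.baseline.total_use_days, params)
legal = accident_burden(shift.shifted.total_use_days, params)
print(f"additional road fatalities: {legal.fatalities - base.fatalities:.1f}")
print(f"additional serious injuries: {legal.injuries['major'] - base.injuries['major']:.0f}")

print("\nmodelled components vs ledger rows (millions, 2007 AUD):")
frame = modelled_components(config)
print(frame.to_string(index=False, float_format=lambda v: f"{v:10.2f}"))
print(
    "\nRead: every modelled value sits inside its row's [low, high] range;\n"
    "rows the model takes as given (criminal-justice costings etc.) are not shown."
)
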