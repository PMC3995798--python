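"""The wellbeing proxy and the price-elasticity thought experiment.

Consumer wellbeing from cannabis is valued as eligible quantity times the
median street price ($20/g), excluding grams consumed by people under 21
or with a cannabis use disorder.
"""

from cannabis_cba import consumption_shift, default_config, elasticity_scenario, wellbeing_value

config = default_config()
shift = consumption_shift(config)
price = config.price_per_gram

for policy, profile in (
    ("status quo", shift.baseline),
    ("legalised-regulated", shift.shifted),
):
    key = policy.replace(" ", "_").replace("-", "_")
    excluded = config.excluded_share(key) * profile.total_grams
    value = wellbeing_value(profile, price, excluded)
    print(f"{policy:<22} wellbeing {value:7.1f} m  "
          f"(total {profile.total_grams / 1e6:.1f} t, excluded {excluded / 1e6:.1f} t)")

base = 645.5  # legalised wellbeing main, millions
down = elasticity_scenario(base, -0.5, 0.5)
up = elasticity_scenario(base, +0.5, 0.5)
print(f"\n50% price fall,  elasticity 0.5: {down:.1f} m")
print(f"50% price rise,  elasticity 0.5: {up:.1f} m")
print(
    "\nRead: at constant price the legalised wellbeing proxy is $645.5m; if the\n"
    "price halved (rose 50%) and quantity responded with elasticity 0.5, the\n"
    "quantity valued at the original price would be worth ~$807m (~$484m)."
)
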