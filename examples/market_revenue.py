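"""The legalised supply side: retail monopoly accounts and public costs.

330 cannabis-only shops sell at the unchanged street price; growers are
paid a farm-gate price; 15% of potential revenue leaks to the black market
and home growing.
"""

from cannabis_cba import market_summary

summary = market_summary()
statement = summary["statement"]
print("annual retail accounts (millions, 2007 AUD):")
print(f"  gross revenue (after 15% leakage)  {statement.gross_millions:8.1f}")
print(f"  payments to growers                {-statement.grower_payments_millions:8.1f}")
print(f"  shop operating costs               {-statement.operating_cost_millions:8.2f}")
print(f"  net government revenue             {statement.net_millions:8.1f}")
print(f"  (revenue leaked to black market    {statement.leaked_millions:8.1f})")

print(f"\npersonal licensing cost: {summary['licence_cost_millions']:.1f} m")
print("public cost components:")
for name, value in summary["public_costs"].items():
    print(f"  {name:<22} {value:6.2f} m")
low, high = summary["greenhouse_receipts_range_millions"]
print(f"grower receipts per one-acre greenhouse: {low:.1f} to {high:.1f} m/year")
print(
    "\nRead: the monopoly collects ~$660m net per year, but revenue is a\n"
    "transfer payment and is excluded from the default net social benefit."
)
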