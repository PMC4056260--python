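"""The comparator arm's intravenous sliding scale, row by row.

Maps blood-glucose values to the protocol's fixed infusion rates and shows
the physician-notification bands, plus the hourly nurse cycle holding the
rate between measurements.
"""

from iculoop.sliding_scale import NurseProtocol, lookup_rate

print(f"{'BG (mM)':>8} {'rate (U/h)':>11} {'notify':>7}")
for bg in (3.5, 4.5, 6.0, 8.0, 9.5, 10.5, 12.0, 15.0, 18.0, 22.0):
    r = lookup_rate(bg)
    print(f"{bg:>8.1f} {r.rate:>11.1f} {'yes' if r.notify else '':>7}")

print("\nnurse cycle, hourly BG 11.5 -> 12.5 -> 13.0 (escalation enabled):")
nurse = NurseProtocol(escalation=True)
for hour, bg in enumerate((11.5, 12.5, 13.0)):
    rate = nurse.hourly(hour * 60.0, bg)
    print(f"  h={hour}: BG {bg:.1f} mM -> {rate:.1f} U/h "
          f"(scale shift {nurse.scale_shift:+d})")
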