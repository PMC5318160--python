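"""Compute dim-light melatonin onset (DLMO) and anchor sample phases to it.

Builds a toy hourly melatonin profile, locates the first ascending crossing
of the 25%-of-range threshold, and converts blood-draw clock times into
circadian phases (15 degrees per hour past onset).
"""

from circaphase import MelatoninSeries, assign_phase, compute_dlmo

series = MelatoninSeries(
    participant_id="P001",
    condition="in_phase",
    times_h=[20, 21, 22, 23, 24],
    concentrations=[2, 2, 2, 10, 10],  # pg/ml
)

dlmo = compute_dlmo(series)
print(f"baseline  {dlmo.baseline:.2f} pg/ml  (mean of the lowest quartile)")
print(f"amplitude {dlmo.amplitude:.2f} pg/ml  (maximum concentration)")
print(f"threshold {dlmo.threshold:.2f} pg/ml  (baseline + 25% of the range)")
print(f"DLMO      {dlmo.dlmo_time_h:.2f} h    (linear interpolation of the crossing)")

for t in (22.25, 4.25, 10.25):
    print(f"sample drawn at {t:5.2f} h -> circadian phase {assign_phase(t, dlmo):6.1f} deg")

# The threshold crosses between the 22:00 (2 pg/ml) and 23:00 (10 pg/ml)
# samples, a quarter of the way up: DLMO = 22.25 h = 0 degrees. A draw 6 h
# later sits at 90 degrees, 12 h later at 180 degrees.
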