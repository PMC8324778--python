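"""Extract the five standard parameters from a thrombin generation curve.

Builds a control-like synthetic TG curve, writes/reads it through the CSV
round trip, and prints lag time, time-to-peak, peak height, ETP and
velocity index.
"""

import tempfile
from pathlib import Path

from thrombodyn import (
    CohortSpec,
    compute_tg_parameters,
    read_tg_curve,
    write_tg_curve,
)
from thrombodyn.synthetic import generate_cohort

sample = generate_cohort(CohortSpec(seed=1, n_controls=1, n_patients=0))[0]

with tempfile.TemporaryDirectory() as d:
    path = write_tg_curve(sample.curve, Path(d) / "control.csv")
    curve = read_tg_curve(path)

p = compute_tg_parameters(curve)
print(f"lag time       {p.lag_time:6.2f} min   (time until thrombin burst begins)")
print(f"time-to-peak   {p.time_to_peak:6.2f} min   (time of maximal free thrombin)")
print(f"peak height    {p.peak_height:6.1f} nM    (maximal free thrombin)")
print(f"ETP            {p.etp:6.0f} nM*min (total thrombin work, area under curve)")
print(f"velocity index {p.velocity_index:6.1f} nM/min (mean rise rate from lag to peak)")
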