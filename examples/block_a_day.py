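"""Block one day of minute-level MET data into activity bouts.

Builds a sedentary day containing a 25-minute run and a 40-minute run
interrupted by a 4-minute rest, runs the blocking algorithm, and prints
each detected block.
"""

import numpy as np
import pandas as pd

from metbout import BlockingConfig, find_blocks, is_valid_block

start = pd.Timestamp("2012-06-04 00:00")
met = np.full(1440, 1.2)                      # resting all day ...
met[480:505] = 5.0                            # ... except a 25-min brisk bout
met[600:618] = 4.2                            # and a 40-min bout with a
met[618:622] = 2.0                            # 4-minute rest in the middle
met[622:640] = 4.2

day = pd.DataFrame(
    {
        "timestamp": start + pd.to_timedelta(np.arange(1440), unit="m"),
        "met": met,
        "on_body": True,
        "imputed": False,
    }
)

ok, reason = is_valid_block(met[600:640], BlockingConfig())
print(f"40-min window with one 4-min rest valid? {ok} (reason: {reason})")

for b in find_blocks(day, BlockingConfig(), participant_id="P001"):
    print(
        f"block {b.start:%H:%M}-{b.end:%H:%M}: {b.duration_minutes} min, "
        f"{b.met_minutes:.0f} MET-min, {b.n_rest_minutes} rest min"
    )
# Each line is one detected bout of >= 10 minutes; MET-minutes sum the
# supra-threshold (>= 3.3 MET) minutes, the currency of weekly scores.
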