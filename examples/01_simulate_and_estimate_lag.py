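"""Simulate a paired EEG-fNIRS session and recover the injected lag.

The generator plants class-specific 8-30 Hz oscillations on a subset of EEG
channels during each task period; the oscillation envelope, convolved with a
canonical double-gamma HRF and delayed by `lag_s`, drives HbO on spatially
matching fNIRS channels.  A matched-filter cross-correlation should read the
lag straight back off the raw recording.
"""

import numpy as np

from bistfnet import (SimulationConfig, estimate_lag, make_montage,
                      simulate_session)

config = SimulationConfig(n_trials_per_class=5, class_labels=(0, 1),
                          lag_s=5.0, snr_db=20.0, seed=7)
montages = make_montage(n_eeg=30, n_fnirs=36, seed=7)
pair = simulate_session(config, montages)

print(f"session: {pair.duration_s:.0f} s, {pair.eeg.shape[0]} EEG ch @ "
      f"{pair.fs_eeg:.0f} Hz, {pair.fnirs_hbo.shape[0]} fNIRS ch @ "
      f"{pair.fs_fnirs:.0f} Hz, {len(pair.events)} trials")

est = estimate_lag(pair, config)
print(f"injected lag: {config.lag_s:.1f} s   estimated lag: {est:.1f} s")
# The estimate should equal the injected 5.0 s to within one fNIRS sample
# (0.1 s): the hemodynamic delay is identifiable from the raw data alone.
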