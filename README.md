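# bibvent

A digital twin of a **bag-in-bottle emergency ventilator**: a pneumatic
device that ventilates a patient by pressurising a sealed chamber (the
"bottle") around a standard 1 L self-inflating resuscitator bag. Chamber
pressure squeezes the bag and drives gas into the patient; expiration is
passive through a threshold PEEP valve while the chamber vents and the bag
self-refills. The only actuator the control firmware owns is the fraction
of supply pressure applied to the chamber, and the firmware adjusts it
**once per breath** from the tidal-volume error — a deliberately simple,
robust control architecture for a device built from anaesthesia-supply-chain
parts.

The package simulates the full closed loop — pneumatic plant, a linear
single-compartment patient lung, and a discrete 25 Hz firmware — and
reproduces the device's design-verification experiments (maximum achievable
therapy, supply-pressure variation, endurance) plus the agreement statistics
used to evaluate it.

## What is in the box

| Module | Purpose |
| --- | --- |
| `bibvent.settings` | Ventilation settings, safety-envelope validation, breath timing arithmetic |
| `bibvent.plant` | Bag-in-bottle pneumatics + single-compartment lung, explicit-Euler integration |
| `bibvent.control` | Per-breath velocity-form PID, PEEP estimator with auto-regressive baseline, patient-trigger detection, pressure limiting, the closed-loop runner |
| `bibvent.verify` | Scripted design-verification experiments (max therapy, supply pressure, endurance, step response) |
| `bibvent.stats` | Bland-Altman limits of agreement, breath segmentation and per-breath metrics |
| `bibvent.wavio`, `bibvent.fixtures`, `bibvent.cli` | Waveform CSV / config JSON I/O, seeded synthetic waveforms, command line |

## Worked example

Ventilate the standard ARDS test lung (airway resistance 20 cmH2O/(L/s),
compliance 17.7 mL/cmH2O) in volume-controlled mode:

```python
from bibvent import PlantParams, VentSettings, run_ventilation
from bibvent.verify import ARDS_TEST_LUNG

settings = VentSettings(vt_target=450, rr=20, peep_set=5.0)
samples, breaths = run_ventilation(settings, PlantParams(), ARDS_TEST_LUNG, 30.0)
for b in breaths:
    print(f"breath {b.index}: VT {b.vt_delivered:.1f} mL  "
          f"PEEP {b.peep_measured:.2f}  Ppeak {b.p_peak:.1f}")
```

Output — the once-per-breath controller walks the delivered volume up to
the target over a handful of cycles, overdamped by design:

```
breath 1: VT 243.8 mL  PEEP 5.18  Ppeak 20.3
breath 2: VT 344.0 mL  PEEP 5.26  Ppeak 26.9
breath 3: VT 355.9 mL  PEEP 5.27  Ppeak 27.8
breath 4: VT 383.0 mL  PEEP 5.30  Ppeak 29.6
breath 5: VT 398.4 mL  PEEP 5.31  Ppeak 30.6
breath 6: VT 411.2 mL  PEEP 5.32  Ppeak 31.5
breath 7: VT 420.5 mL  PEEP 5.32  Ppeak 32.1
breath 8: VT 427.9 mL  PEEP 5.33  Ppeak 32.6
breath 9: VT 433.4 mL  PEEP 5.33  Ppeak 32.9
```

The same runs are available from the command line:

```bash
bibvent verify max-therapy
bibvent verify supply-pressure --preset decreasing
bibvent verify endurance --days 30 --json
```

which on this plant prints, respectively, the high-flow capability sweep
(configurations needing up to 810 mL/s pass within ±10%; 900 and
1200 mL/s exceed the 825 mL/s bag-outflow limit and fail), the
supply-pressure series (4 bar: worst 2.2% PASS; 3.5 bar: 11.5% FAIL;
3 bar: 19.7% FAIL — see `docs/methods.md` on the 3.5 bar margin), and the
endurance surrogate (`{"days_within_bounds": 23, "failure_day": 24}`).

## Model, units and limitations

Pressures are in cmH2O (supply pressure in bar), volumes in mL, flows in
mL/s, time in s. The model, its parameters and its known limitations —
including why the plant cannot reach some pressure-hungry corner cases a
physical bench can — are documented in [`docs/methods.md`](docs/methods.md).

This is a simulation for engineering analysis and education. It is **not**
a medical device and must not be used to guide patient care.
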