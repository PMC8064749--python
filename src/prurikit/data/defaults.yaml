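# Default parameters of the synthetic-data generators.
#
# Heat-response and injection shapes are qualitative models of the recorded
# discharge patterns (boxcar burst + exponential adaptation for QC; smooth
# plateau-phase peak for SC; exponentially decaying pruritogen-evoked rate).
# Target net-AP means are rounded from the reported QC/SC population cell
# means; response probabilities from the reported responder incidences.

heat:
  QC:
    burst_rate_hz: 80.0      # discharge rate during the temperature ramp
    burst_start_frac: 0.2    # burst begins this fraction into the ramp
    adapt_tau_s: 0.6         # exponential adaptation during the plateau
  SC:
    max_rate_hz: 50.0        # peak discharge rate, reached in the plateau
    peak_after_rise_s: 1.5   # rate peak this long after the end of the ramp
    shape: 2.0               # gamma-shape of the rate rise/decay
latency:
  min_s: 0.1                 # conduction latency from skin, uniform draw;
  max_s: 0.5                 # consistent with C-fiber CV < 2 m/s over a few cm

injection:
  spontaneous_rate_hz: 0.02  # CMHs are near-silent at rest
  injection_duration_s: 5.0
  artifact_spikes_mean: 2.0  # spikes during needle insertion / injection
  observation_s: 300.0
  vehicles: [ECF, BAM8_18]
  target_net_aps:            # population mean net response per 5 min
    QC: {ALA: 83.0, BAM8_22: 52.0}
    SC: {ALA: 10.0, BAM8_22: 94.0}
  decay_tau_s:               # evoked-discharge decay time constants
    QC: {ALA: 60.0, BAM8_22: 45.0}
    SC: {ALA: 25.0, BAM8_22: 90.0}
  response_prob:             # responder incidence per fiber type
    QC: {ALA: 0.93, BAM8_22: 0.72}
    SC: {ALA: 0.23, BAM8_22: 0.94}
  amplitude_shape: 2.0       # gamma shape of per-responder amplitudes

ratings:
  rise_tau_min: 0.35         # rating curves peak 1-2 min post-injection
  decay_onset_min: 1.0
  noise_sd: 1.5
  rating_floor: 0.5          # percepts below this register as zero
  gain_sigma: 0.35           # log-normal subject gain
  mean_peak:                 # gLMS magnitude of the mean curve at its peak
    itch:              {ALA: 28.0, BAM: 26.0, HIS: 34.0, BAM+ALA: 30.0, BAM+ALA+HIS: 36.0}
    pricking_stinging: {ALA: 18.0, BAM: 16.0, HIS: 17.0, BAM+ALA: 19.0, BAM+ALA+HIS: 20.0}
    burning:           {ALA: 14.0, BAM: 13.0, HIS: 15.0, BAM+ALA: 15.0, BAM+ALA+HIS: 16.0}
  itch_decay_tau_min:        # histamine itch declines much more slowly
    ALA: 4.0
    BAM: 4.0
    HIS: 8.0
    BAM+ALA: 4.0
    BAM+ALA+HIS: 8.0
  pain_decay_tau_min: 3.0    # pricking/stinging and burning fade faster

areas:
  base_cm2:                  # log-normal median area per measure
    alloknesis: 20.0
    hyperalgesia: 15.0
    hyperknesis: 12.0
    wheal: 1.5
    flare: 10.0
  his_multiplier: 3.0        # HIS-containing stimuli produce larger areas
  sigma: 0.5

puncta:
  species: human
  n_donors: 4
  neurons_per_donor: 150
  joint:                     # joint marker-state probabilities (sum to 1);
                             # MRGPRX1+ implies TRPV1+ in the default panel
    - {MRGPRD: true,  MRGPRX1: true,  TRPV1: true,  p: 0.30}
    - {MRGPRD: true,  MRGPRX1: false, TRPV1: true,  p: 0.03}
    - {MRGPRD: false, MRGPRX1: true,  TRPV1: true,  p: 0.02}
    - {MRGPRD: false, MRGPRX1: false, TRPV1: true,  p: 0.25}
    - {MRGPRD: true,  MRGPRX1: false, TRPV1: false, p: 0.01}
    - {MRGPRD: false, MRGPRX1: false, TRPV1: false, p: 0.39}
  positive_mean: 25.0        # negative-binomial puncta counts per state
  positive_shape: 5.0
  negative_mean: 0.8
  negative_shape: 1.0
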