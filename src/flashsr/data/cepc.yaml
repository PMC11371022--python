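# CEPC Higgs-mode storage ring and bending-magnet parameters.
# The beam current is the CDR design value; all other machine numbers are
# the published storage-ring and bending-magnet figures.  The two
# reference mean dose rates are the simulated beamline values at the
# phantom (with and without low-energy filters); they are inputs here,
# not recomputed.
machine:
  electron_energy: 120.0        # GeV
  bend_radius: 10700.0          # m
  beam_current: 17.4            # mA (CDR design value; not printed with the source figures)
  bend_angle: 2.844e-3          # rad
  n_bunches: 242
  revolution_frequency: 3003.0  # Hz
  bunch_duration: 14.7e-12      # s
  sigma_x: 2.09e-2              # mm
  sigma_y: 6.8e-5               # mm
  emittance_x: 1.21             # nm rad
  emittance_y: 3.1e-3           # nm rad
reference:
  published_photon_rate_per_metre: 2.363e16   # photons m^-1 s^-1
  dose_rate_with_filters: 6.13e6              # Gy/s, mean, at phantom
  dose_rate_without_filters: 1.06e7           # Gy/s, mean, at phantom
  mean_energy_with_filters_keV: 307.0
  mean_energy_without_filters_keV: 134.0
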