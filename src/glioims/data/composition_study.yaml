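# Study-condition composition profiles for the synthetic IMS generator.
#
# Class shares are fractions of total ion current within one polarity and sum
# to 1 per polarity. Per-arm class changes are expressed as fold factors
# applied to the healthy-vehicle baseline: classes under `increase`/`decrease`
# are scaled, classes under `held` keep their share, and all remaining classes
# absorb the residual pro rata so shares stay normalised.
#
# Species values are within-class mole percentages; species of a class not
# listed share the remaining percentage uniformly. The named values encode the
# published composition of the proliferative (MKI67+) cluster per study arm:
# GBM vs healthy class changes (PE 1.5x, PI 3.6x, SM 1.8x up; Sulf 2.9x down),
# TMZ vs vehicle in healthy tissue (PI 2.2x up; HexCer 1.8x, Sulf 1.6x down),
# and the species tables (e.g. PI 38:4 at 54.9% healthy / 75.7% GBM / 80.4%
# TMZ-treated healthy; diacyl PE 36:1 at 35.6% healthy; PE P-36:2 at 20.8%
# healthy vs 3.6% GBM). `bulk_tissue` is a white-matter-like, sulfatide-rich
# profile used for the non-proliferative parenchyma region of every section.

class_shares:
  healthy_vehicle:
    negative: {PE: 0.15, "PE P-": 0.15, PI: 0.06, PS: 0.22, PG: 0.10, Sulf: 0.32}
    positive: {PC: 0.55, SM: 0.10, HexCer: 0.20, DG: 0.06, TG: 0.09}
  bulk_tissue:
    negative: {PE: 0.06, "PE P-": 0.06, PI: 0.03, PS: 0.10, PG: 0.05, Sulf: 0.70}
    positive: {PC: 0.30, SM: 0.12, HexCer: 0.46, DG: 0.04, TG: 0.08}

class_fold_changes:
  gbm_vehicle:
    increase: {PE: 1.5, PI: 3.6, SM: 1.8}
    decrease: {Sulf: 2.9}
    held: ["PE P-"]
  healthy_tmz:
    increase: {PI: 2.2}
    decrease: {Sulf: 1.6, HexCer: 1.8}
    held: ["PE", "PE P-", "SM"]
  gbm_tmz:
    base: gbm_vehicle
    increase: {}
    decrease: {}
    held: []

# Within-class mole % (named species; the rest of the class panel shares the
# remainder uniformly). Classes not listed for an arm fall back to `common`.
species_pct:
  common:
    PC: {"34:1": 30.0, "36:1": 15.0, "32:0": 12.0, "36:2": 8.0, "38:4": 6.0,
         "38:6": 6.0, "40:6": 5.0}
    PS: {"36:1": 40.0, "40:6": 20.0, "38:4": 10.0, "36:2": 8.0}
    PG: {"34:1": 30.0, "36:2": 20.0, "36:1": 15.0}
    HexCer: {"d42:2": 30.0, "d42:1": 20.0, "d36:1": 15.0, "d34:1": 10.0}
    DG: {"34:1": 40.0, "36:2": 25.0}
    TG: {"52:2": 30.0, "54:3": 25.0, "50:1": 20.0}

  healthy_vehicle:
    PE: {"36:1": 35.6, "40:6": 13.9, "38:4": 11.3, "38:1": 6.1, "34:0": 3.2,
         "36:2": 8.0, "36:4": 2.0, "38:5": 3.0}
    "PE P-": {"36:2": 20.8, "38:4": 14.7, "34:1": 13.7, "40:6": 10.2,
              "40:5": 7.1, "38:6": 2.8, "36:4": 1.9, "40:7": 1.8, "40:4": 9.0}
    PI: {"38:4": 54.9, "38:5": 5.1}
    SM: {"d36:1": 41.0, "d42:2": 26.8, "d34:1": 10.6, "d38:1": 6.0,
         "d42:1": 4.0, "d44:2": 3.0, "d36:2": 3.0}
    Sulf: {"d42:2": 50.8, "t42:1": 15.9, "d42:1": 11.3, "d44:2": 6.0,
           "d36:3": 2.0, "d36:2": 1.5, "d36:4": 1.0}

  gbm_vehicle:
    PE: {"36:1": 30.0, "38:4": 13.4, "36:2": 10.1, "40:6": 10.0, "34:0": 6.0,
         "36:4": 6.0, "38:1": 5.0, "38:5": 3.0}
    "PE P-": {"38:4": 22.0, "36:4": 14.8, "40:6": 10.4, "38:6": 10.3,
              "36:2": 3.6, "40:5": 4.3, "34:1": 6.0, "40:4": 8.0, "40:7": 2.5}
    PI: {"38:4": 75.7, "38:5": 5.0}
    SM: {"d34:1": 37.5, "d36:1": 26.6, "d36:2": 8.3, "d40:1": 6.0,
         "d42:2": 10.0, "d38:1": 4.0}
    Sulf: {"d42:2": 23.9, "d36:3": 21.0, "d36:4": 11.4, "d36:2": 8.0,
           "d34:1": 6.0, "t42:1": 5.0, "d42:1": 4.0, "d44:2": 2.0}

  healthy_tmz:
    PE: {"36:1": 27.1, "40:6": 23.2, "38:4": 15.8, "34:0": 5.5, "38:1": 4.0,
         "36:2": 8.0, "36:4": 2.0, "38:5": 3.0}
    "PE P-": {"40:6": 23.5, "38:4": 20.4, "40:4": 11.5, "36:2": 7.3,
              "38:6": 6.5, "40:5": 7.0, "34:1": 5.0, "40:7": 3.2, "36:4": 2.5}
    PI: {"38:4": 80.4, "38:5": 6.3}
    SM: {"d36:1": 50.1, "d38:1": 12.4, "d42:2": 12.1, "d34:1": 10.0}
    Sulf: {"d42:2": 49.0, "t42:1": 15.0, "d42:1": 10.5, "d44:2": 5.0,
           "d36:2": 3.5, "d36:3": 2.0, "d36:4": 1.0}

  gbm_tmz:
    base: gbm_vehicle
    overrides:
      PE: {"38:5": 6.0}

  bulk_tissue:
    PE: {"36:1": 45.0, "40:6": 8.0, "38:4": 8.0}
    "PE P-": {"34:1": 30.0, "36:1": 20.0, "36:2": 10.0}
    PI: {"38:4": 40.0, "36:1": 15.0}
    PS: {"36:1": 55.0, "40:6": 20.0}
    SM: {"d42:2": 40.0, "d36:1": 20.0, "d42:1": 15.0}
    Sulf: {"d42:2": 30.0, "d42:1": 20.0, "t42:1": 20.0, "d44:2": 15.0,
           "d40:1": 10.0}
    HexCer: {"d42:2": 30.0, "d42:1": 25.0, "t42:1": 15.0, "d40:1": 10.0,
             "d36:1": 10.0}

noise:
  sigma: 0.3               # log-normal multiplicative intensity noise (log-sd)
  mz_jitter_ppm: 3.0       # uniform half-width of per-peak mass error
  background_tic_fraction: 0.01
  background_peaks: [5, 20]
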