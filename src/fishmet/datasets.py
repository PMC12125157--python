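"""Published category-level summary statistics for metals in Bangladeshi fish.

These are the compiled literature summaries of metal(loid) concentrations
(ug/g fresh weight) in dietary fish of Bangladesh, aggregated per species
and then summarized by habitat class and by feeding class.  They serve two
roles in this package:

* as printed inputs for reproducing the published exposure and risk
  figures (the risk engine applied to a category mean vector), and
* as calibration targets for the synthetic-record generator, whose default
  stratum means and standard deviations are read from here.

Values are category-level statistics over species-level weighted means,
not raw records.
"""

from __future__ import annotations

from .toxdata import Feeding, Habitat, Metal

# mean concentration (ug/g fresh weight) per habitat class
HABITAT_MEAN: dict[Habitat, dict[Metal, float]] = {
    Habitat.freshwater: {
        Metal.As: 0.17, Metal.Cd: 0.09, Metal.Cr: 1.25, Metal.Cu: 2.60,
        Metal.Hg: 0.09, Metal.Mn: 3.84, Metal.Ni: 0.89, Metal.Pb: 0.95,
        Metal.Zn: 27.90,
    },
    Habitat.saltwater: {
        Metal.As: 0.50, Metal.Cd: 1.00, Metal.Cr: 0.63, Metal.Cu: 1.39,
        Metal.Hg: 0.90, Metal.Mn: 1.05, Metal.Ni: 0.45, Metal.Pb: 1.14,
        Metal.Zn: 7.40,
    },
    Habitat.euryhaline: {
        Metal.As: 0.35, Metal.Cd: 0.11, Metal.Cr: 0.98, Metal.Cu: 1.29,
        Metal.Hg: 0.14, Metal.Mn: 1.62, Metal.Ni: 0.46, Metal.Pb: 1.19,
        Metal.Zn: 12.26,
    },
}

HABITAT_SD: dict[Habitat, dict[Metal, float]] = {
    Habitat.freshwater: {
        Metal.As: 0.23, Metal.Cd: 0.16, Metal.Cr: 1.87, Metal.Cu: 3.14,
        Metal.Hg: 0.15, Metal.Mn: 6.02, Metal.Ni: 1.61, Metal.Pb: 1.27,
        Metal.Zn: 38.50,
    },
    Habitat.saltwater: {
        Metal.As: 0.87, Metal.Cd: 3.01, Metal.Cr: 0.83, Metal.Cu: 1.76,
        Metal.Hg: 2.37, Metal.Mn: 2.33, Metal.Ni: 1.37, Metal.Pb: 2.10,
        Metal.Zn: 7.12,
    },
    Habitat.euryhaline: {
        Metal.As: 0.39, Metal.Cd: 0.14, Metal.Cr: 1.29, Metal.Cu: 1.43,
        Metal.Hg: 0.29, Metal.Mn: 3.26, Metal.Ni: 0.46, Metal.Pb: 1.46,
        Metal.Zn: 20.44,
    },
}

# number of species-level data points behind each habitat/metal cell
HABITAT_N: dict[Habitat, dict[Metal, int]] = {
    Habitat.freshwater: {
        Metal.As: 62, Metal.Cd: 57, Metal.Cr: 62, Metal.Cu: 57, Metal.Hg: 47,
        Metal.Mn: 45, Metal.Ni: 47, Metal.Pb: 64, Metal.Zn: 50,
    },
    Habitat.saltwater: {
        Metal.As: 28, Metal.Cd: 25, Metal.Cr: 29, Metal.Cu: 27, Metal.Hg: 15,
        Metal.Mn: 22, Metal.Ni: 17, Metal.Pb: 29, Metal.Zn: 26,
    },
    Habitat.euryhaline: {
        Metal.As: 9, Metal.Cd: 9, Metal.Cr: 10, Metal.Cu: 9, Metal.Hg: 7,
        Metal.Mn: 8, Metal.Ni: 9, Metal.Pb: 10, Metal.Zn: 10,
    },
}

FEEDING_MEAN: dict[Feeding, dict[Metal, float]] = {
    Feeding.omnivorous: {
        Metal.As: 0.24, Metal.Cd: 0.14, Metal.Cr: 1.28, Metal.Cu: 2.55,
        Metal.Hg: 0.11, Metal.Mn: 2.96, Metal.Ni: 1.10, Metal.Pb: 1.01,
        Metal.Zn: 24.32,
    },
    Feeding.carnivorous: {
        Metal.As: 0.29, Metal.Cd: 0.64, Metal.Cr: 0.83, Metal.Cu: 1.47,
        Metal.Hg: 0.80, Metal.Mn: 1.61, Metal.Ni: 0.42, Metal.Pb: 1.04,
        Metal.Zn: 11.02,
    },
    Feeding.herbivorous: {
        Metal.As: 0.18, Metal.Cd: 0.05, Metal.Cr: 1.00, Metal.Cu: 2.86,
        Metal.Hg: 0.07, Metal.Mn: 5.13, Metal.Ni: 0.39, Metal.Pb: 0.68,
        Metal.Zn: 32.40,
    },
}

FEEDING_SD: dict[Feeding, dict[Metal, float]] = {
    Feeding.omnivorous: {
        Metal.As: 0.39, Metal.Cd: 0.30, Metal.Cr: 1.86, Metal.Cu: 3.37,
        Metal.Hg: 0.18, Metal.Mn: 4.71, Metal.Ni: 1.96, Metal.Pb: 1.42,
        Metal.Zn: 30.24,
    },
    Feeding.carnivorous: {
        Metal.As: 0.39, Metal.Cd: 2.46, Metal.Cr: 1.46, Metal.Cu: 1.64,
        Metal.Hg: 2.18, Metal.Mn: 3.14, Metal.Ni: 0.50, Metal.Pb: 1.60,
        Metal.Zn: 13.82,
    },
    Feeding.herbivorous: {
        Metal.As: 0.25, Metal.Cd: 0.06, Metal.Cr: 1.53, Metal.Cu: 2.64,
        Metal.Hg: 0.10, Metal.Mn: 7.94, Metal.Ni: 0.44, Metal.Pb: 1.07,
        Metal.Zn: 55.39,
    },
}
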