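#!/usr/bin/env python
"""Simulate every input of the droplet-volume / ddPCR analysis.

Generates, with known ground truth:
  * three hierarchical droplet-diameter tables (two DG8-style manual
    generators and one DG32-style automated generator, 6 wells x 3 days);
  * a set of bright-field-like monolayer micrographs for one well;
  * a duplex two-generator ddPCR wells table (18 sample replicates per
    generator plus negative template controls).

Bulky intermediates go to scratch/ (regenerate by re-running); downstream
scripts read them from there.
"""

from pathlib import Path

import tifffile

from dropvol.synthetic import (
    HierarchicalDiameterSpec,
    ImageSpec,
    generate_droplet_image,
    generate_duplex_wells,
    generate_hierarchical_diameters,
)
from dropvol.volume_stats import diameter_from_volume

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
IMAGES = ROOT / "scratch" / "images"
SEED = 20170918

#: mean droplet volumes (nL) of the three experimental set-ups being emulated
SETUP_MEAN_VOLUME_NL = {"DG8-NIB": 0.715, "DG8-INRIM": 0.720, "DG32": 0.739}

GROUP_MEANS = {
    "DG8": {"A2704-12": 115_351.0, "Le1": 119_230.0},
    "DG32": {"A2704-12": 114_131.0, "Le1": 117_369.0},
}


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    IMAGES.mkdir(parents=True, exist_ok=True)

    for i, (setup, mean_v) in enumerate(SETUP_MEAN_VOLUME_NL.items()):
        spec = HierarchicalDiameterSpec(mean_diameter_um=float(diameter_from_volume(mean_v)))
        table = generate_hierarchical_diameters(spec, seed=SEED + i)
        out = DATA / f"{setup.lower().replace('-', '_')}_diameters.csv"
        table.to_csv(out, index=False)
        print(f"{setup}: {len(table)} droplets, grand mean "
              f"{table.diameter_um.mean():.2f} um -> {out.relative_to(ROOT)}")

    # six micrographs of one well (~60 droplets each), plus truth tables
    for j in range(6):
        spec = ImageSpec(shape=(2600, 2600), pixel_size_um=0.5, n_droplets=60, noise_sd=8.0)
        img, truth = generate_droplet_image(spec, seed=SEED + 100 + j)
        tifffile.imwrite(IMAGES / f"well1_frame{j}.tif", img)
        truth.to_csv(IMAGES / f"well1_frame{j}.truth.csv", index=False)
    print(f"6 micrographs (60 droplets each, noise SD 8 grey levels) -> {IMAGES.relative_to(ROOT)}")

    wells = generate_duplex_wells(GROUP_MEANS, seed=SEED + 200, deterministic=True)
    wells.to_csv(DATA / "wells.csv", index=False)
    n_ntc = int(wells.is_ntc.sum() / 2)
    print(f"wells table: {wells.well.nunique()} wells ({n_ntc} NTCs), 2 targets "
          f"-> {(DATA / 'wells.csv').relative_to(ROOT)}")


if __name__ == "__main__":
    main()
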