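#!/usr/bin/env python
"""Generate the synthetic study inputs with exported ground truth.

Writes to results/data/:
  * the reference component library (10 Gaussian-band cell-wall
    component spectra on the 1800-800 cm^-1 fingerprint axis),
  * a bulk ATR genotype panel (5 easy- / 10 difficult-to-root
    genotypes x 6 replicate spectra, seed 7) with a +40% mannose
    signature planted in the easy group and rooting traits generated
    from that compound's weight,
  * an ENVI cube pair (96x96, seed 1): a reference stem cross-section
    and one with a +50% mannose shift planted in the root cap,
  * ground-truth files (region labels, genotype weights, traits).
"""

from pathlib import Path

from stemftir.io_spectra import write_envi, write_metadata_csv, write_spectra_csv
from stemftir.synth import SynthConfig, make_cube_pair, make_library, make_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel_cfg = SynthConfig(seed=7)
    library = make_library(panel_cfg)
    library.to_csv(OUT / "library.csv")
    print(f"library: {library.n_components} components x {len(library.axis)} channels")

    panel, panel_truth = make_panel(panel_cfg, library)
    write_spectra_csv(panel, OUT / "panel.csv", layout="wide")
    write_metadata_csv(panel.meta, OUT / "panel_meta.csv")
    panel_truth.save(OUT, "panel")
    genotypes = sorted({m.genotype for m in panel.meta})
    print(f"panel: {panel.n_samples} spectra, {len(genotypes)} genotypes (seed 7)")

    cube_cfg = SynthConfig(seed=1)
    cube_lib = make_library(cube_cfg)
    cube_lib.to_csv(OUT / "library_imaging.csv")
    (ref, truth_ref), (eff, truth_eff) = make_cube_pair(cube_cfg, library=cube_lib)
    write_envi(ref, OUT / "cube_reference.hdr")
    write_envi(eff, OUT / "cube_effect.hdr")
    truth_ref.save(OUT, "cube_reference")
    truth_eff.save(OUT, "cube_effect")
    print(
        f"cubes: {ref.shape[0]}x{ref.shape[1]}x{ref.shape[2]} (seed 1), "
        f"planted: {truth_eff.planted_effects}"
    )
    print(f"all inputs written to {OUT}")


if __name__ == "__main__":
    main()
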