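"""Sweep kernels, QIR levels and doses and summarise the results.

Runs a desk-scale factorial (3 kernels x 3 QIR x 2 doses x 2 diameters x
3 concentrations x 2 seeds), prints median noise per (kernel, QIR), the
slope plateau relative to the published reference column, and one
slope-score grid per dose.
"""

from phantomiq import (
    default_desk_config,
    load_kernel_table,
    plateau_summary,
    run_sweep,
    score_grid,
)

config = default_desk_config(seeds=(0, 1))
print(f"running {config.n_cells} cells ...")
result = run_sweep(config)

noise = result.table.pivot_table(index="kernel", columns="qir",
                                 values="noise_sd", aggfunc="median")
print("\nmedian background noise SD (HU) at the swept doses:")
print(noise.round(1))

table = load_kernel_table()
summary = plateau_summary(
    dict(zip(table["name"], table["max_slope_hu_per_mm"])), "Qr76"
)
print("\npublished maximum-slope column relative to Qr76 (%):")
print(summary.per_kernel.round(1).to_string(index=False))
print(f"kernels on the sharpness plateau (<10% loss): {summary.plateau_kernels}")

grids = score_grid(result)
for ctdi, grid in grids.items():
    print(f"\nmedian slope scores at {ctdi:g} mGy "
          "(rows: kernel/QIR, columns: diameter mm / mg I/mL):")
    print(grid)

print("\nNote the 9.25 mg I/mL column: it iso-attenuates with the wall, so no "
      "kernel separates the inner boundary and scores stay at 4.")
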