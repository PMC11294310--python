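"""Simulate one phantom slice and run the edge-profile analysis.

Renders a 3 mm silicone tube filled with 37 mg I/mL iodine, reconstructed
with the sharp Qr60 kernel at QIR-4 and 30 mGy, then measures noise,
amplitude, the slope maxima at the wall boundaries and the 0-8 slope
score.  (Use phantomiq.image_io.save_tiff / save_dicom to export slices.)
"""

from phantomiq import (
    AcquisitionSpec,
    PhantomSpec,
    analyze_image,
    kernel_from_table,
    simulate_slice,
)

phantom = PhantomSpec(inner_diameter=3.0, iodine_concentration=37.0)
kernel = kernel_from_table("Qr60")
acq = AcquisitionSpec(ctdi=30.0, qir_level=4)

image = simulate_slice(phantom, kernel, acq, seed=1)
result = analyze_image(image, phantom)

print(f"phantom: {phantom.inner_diameter:g} mm lumen at {phantom.hu_lumen:.0f} HU, "
      f"{phantom.wall_thickness:g} mm wall at {phantom.hu_silicone:.0f} HU")
print(f"reconstruction: {kernel.name}, QIR-{acq.qir_level}, {acq.ctdi:g} mGy\n")
print(f"measured noise SD:    {result.noise_sd:7.1f} HU")
print(f"profile amplitude:    {result.amplitude:7.1f} HU")
print(f"mean slope maximum:   {result.mean_slope_maximum:7.1f} HU/mm")
print(f"slope score:          {result.slope_score} / 8\n")

print("transitions (profile, side, boundary, slope HU/mm, visible):")
for t in result.transition_maxima:
    print(f"  {t.profile:10} {t.side:6} {t.boundary:5} {t.slope:8.1f}   {t.visible}")

print("\nA score of 8 means every water-wall and wall-lumen boundary produced "
      "its own slope maximum above the noise level — the wall is fully "
      "resolved from the contrast-filled lumen.")
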