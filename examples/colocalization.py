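"""Intensity-independent colocalization on synthetic two-channel fields.

Generates spot fields with a known shared-object fraction and runs the
normalize -> Wiener -> average -> blank -> threshold -> symmetry pipeline.
"""

from cln3topo import colocalization_fraction, generate_coloc_pair

for true_overlap in (0.0, 0.5, 1.0):
    field = generate_coloc_pair(true_overlap, n_objects=200, seed=2,
                                shape=(512, 512))
    res = colocalization_fraction(field.channels[0], field.channels[1],
                                  count_threshold=10, symmetry_cutoff=0.3)
    print(f"true overlap {true_overlap:.1f} -> measured fraction "
          f"{res.fraction:.3f}  ({res.n_colocalized_pixels}/"
          f"{res.n_reference_pixels} reference pixels)")

print()
print("The measured fraction tracks the generator's planted overlap; because")
print("both channels are rescaled to their own maxima the statistic is")
print("insensitive to overall channel brightness.")
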