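"""Locate the excision-repair damage signature in read composition.

Nuclear excised oligomers carry a pyrimidine dinucleotide (the UV lesion)
5-6 nt from their 3' end; mitochondrial reads, which are a specificity
control, do not.  The example prints the per-offset pyrimidine-pair
frequency for both compartments.
"""

from xrquant import composition
from xrquant.read_processing import LengthRange, filter_length, trim_5prime_to
from xrquant.synthetic_data import (SimulationParams, make_genes, make_genome,
                                    simulate_library)

params = SimulationParams(seed=2, n_reads=6_000, mito_fraction=0.12)
genome = make_genome(params)
library = simulate_library(genome, make_genes(genome, params), params)

reads = trim_5prime_to(filter_length(library.aligned, LengthRange(20, 28)), 20)
profiles = composition.compartment_profiles(reads)

for name, prof in profiles.items():
    peak = composition.pyrimidine_peak(prof)
    print(f"{name}: {prof.n_reads} reads, "
          f"pyrimidine-pair peak at 3'-offsets {peak}, "
          f"max/median = {composition.flatness(prof):.2f}")
    frac = prof.pyrimidine_fraction
    for offset in range(1, 9):
        idx = list(prof.offsets_3prime).index(offset)
        bar = "#" * int(frac[idx] * 60)
        print(f"   offset {offset}: {frac[idx]:.3f} {bar}")

print("-> the nuclear library peaks sharply at offsets 5-6 (the 3' incision "
      "signature); the mitochondrial control stays at the ~0.25 chance level")
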