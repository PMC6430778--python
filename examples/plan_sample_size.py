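"""How many radiographs does a dental-age study need?

Evaluates the finite-population proportion formula (with design effect) for
an archive of 420 candidate radiographs at 95% confidence and +/-5%
absolute precision, and shows how the requirement scales with the archive.
"""

from dentalage import required_sample_size

n = required_sample_size(N=420, p=0.5, d=0.05, z=1.96, deff=1.0)
print(f"archive of 420 radiographs, p=0.5, d=0.05, Z=1.96, DEFF=1 -> n = {n}")

for N in (100, 420, 2000, 100000):
    print(f"  N={N:>6} -> required n = {required_sample_size(N=N)}")
print(
    "p=0.5 is the conservative (maximum-variance) choice; the finite-population "
    "correction pulls n far below the infinite-population ~385."
)
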