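# Built-in cyclitol registry. Extend or override with a file of the same
# format passed to load_cyclitol_registry(). pKa values are metadata only.

[d-sorbitol]
formula = C6H14O6
class = linear
mz = 181
ionization = negative

[adonitol]
formula = C5H12O5
class = linear
mz = 153
ionization = positive

[shikimic-acid]
formula = C7H10O5
class = cyclic
pka = 4.1
mz = 173
ionization = negative

[quinic-acid]
formula = C7H12O6
class = cyclic
pka = 3.5
mz = 191
ionization = negative
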