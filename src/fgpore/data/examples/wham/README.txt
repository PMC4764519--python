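Synthetic umbrella campaign drawn from the biased Boltzmann law of the
analytic well U(z) = 0.5 * 2.0 * z^2 (kJ/mol, z in nm) at kBT = 2.494.
Regenerate with scripts in the test suite; used by the CLI wham example.
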