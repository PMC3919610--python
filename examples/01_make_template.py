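"""Build the asymmetric minicircle template and inspect its composition.

The lagging-strand template carries 50x more C than G, so dGTP analogs
(ddGTP, dGDPNP) perturb lagging-strand synthesis while leaving the
C-deficient leading-strand template almost untouched.
"""

from okacycle import concatemer_position, make_minicircle, write_fasta

tpl = make_minicircle(length=409, n_C=200, n_G=4, seed=1)
print(f"length          : {tpl.length} nt")
print(f"composition     : C={tpl.n_C} G={tpl.n_G} A={tpl.n_A} T={tpl.n_T}")
print(f"C:G ratio       : {tpl.n_C / tpl.n_G:.0f}:1   (the asymmetry that makes "
      "dGTP analogs lagging-strand specific)")
print(f"C fraction      : {tpl.n_C / tpl.length:.3f}")
print(f"base at 1000 nt : {concatemer_position(tpl, 1000)} "
      "(rolling-circle concatemer wraps every 409 nt)")

write_fasta(tpl, "minicircle.fasta")
print("wrote minicircle.fasta")
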