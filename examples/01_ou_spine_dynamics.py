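"""Spontaneous spine dynamics as an Ornstein-Uhlenbeck process.

Without reward the synaptic parameters feel only the Gaussian prior and
the temperature-scaled Wiener noise, i.e. an OU process whose stationary
law has mean mu and variance T * sigma^2.  This script simulates an
ensemble with the same integrator the network uses and compares the
empirical moments against theory: the two numbers in each row should agree
within the quoted standard errors.
"""

from synsample.validation import ou_stationary_test

res = ou_stationary_test(n_synapses=10_000, n_updates=20_000, seed=1)
print(f"stationary mean:     {res.mean:+.4f}   (theory {res.expected_mean:+.4f},"
      f" SE {res.se_mean:.4f})")
print(f"stationary variance:  {res.variance:.4f}   (theory T*sigma^2 ="
      f" {res.expected_variance:.4f}, SE {res.se_variance:.4f})")
print("PASS" if res.passed else "FAIL", "- both moments within 3 SE")
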