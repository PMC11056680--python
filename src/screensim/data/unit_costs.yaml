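# Illustrative hourly unit costs per currency.
# The GBP rate is the implied senior-researcher rate backed out of the
# reference cost table (total cost / total hours of the baseline arm); the
# AUD rate is an illustrative mid-level academic rate.  Both are config
# inputs, not constants: replace with rates applicable to your setting.
currencies:
  GBP: 30.129528
  AUD: 52.00
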