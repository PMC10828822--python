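{
  "tmt10": {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.13779,
    "130N": 130.134825,
    "130C": 130.141145,
    "131": 131.13818
  },
  "tmt11": {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.13779,
    "130N": 130.134825,
    "130C": 130.141145,
    "131N": 131.13818,
    "131C": 131.1445
  },
  "tmtpro16": {
    "126C": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.13779,
    "130N": 130.134825,
    "130C": 130.141145,
    "131N": 131.13818,
    "131C": 131.1445,
    "132N": 132.141535,
    "132C": 132.147855,
    "133N": 133.14489,
    "133C": 133.15121,
    "134N": 134.148245
  },
  "tmtpro18": {
    "126C": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.13779,
    "130N": 130.134825,
    "130C": 130.141145,
    "131N": 131.13818,
    "131C": 131.1445,
    "132N": 132.141535,
    "132C": 132.147855,
    "133N": 133.14489,
    "133C": 133.15121,
    "134N": 134.148245,
    "134C": 134.154565,
    "135N": 135.1516
  }
}
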