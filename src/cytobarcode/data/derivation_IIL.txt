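IIL-complex a: a[ed/hi/on/jk/bc]fg/lm/qp/r
IIL-complex b: a[cb]kj/no/ih/defg/lm/qp/r
IIL-complex c: abc[kj/no/ih/defg]lm/qp/r
IIL-complex d: abc[gfed]hi/on/jklm/qp/r
IIL-2: abcdefghi/on/jklm[qp]r
IIL-3: abcdefghi/on[jklm]pqr
IIL-1: abcdefghi[onmlkj]pqr
Standard: abcdefghijklmnopqr
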