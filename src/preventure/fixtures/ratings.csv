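item,WM,TK,MJ
Structure,Poor,Poor,Poor
Consumer,Excellent,Poor,Good
Technology,Excellent,Poor,Good
Financing,Poor,Good,Poor
Public Policy,Non-existent,Good,Poor
Accountability,Poor,Good,Good
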