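code,train,test
C0,2298,611
C1,226,54
C2,441,95
C3,794,191
C4,129,28
C5,54,14
C6,209,48
C7,157,30
C8,361,97
C9,214,51
C10,82,18
C11,139,46
C13,340,83
C14,422,104
C15,335,83
C18,89,22
C19,90,15
C22,44,13
C25,754,188
C27,51,24
C29,66,16
C32,50,17
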