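atom_id,label
0,N1
1,C2
2,C3
3,C7
4,C8
5,C9
6,C10
7,C20
8,N21
9,C11
10,C12
11,C13
12,C14
13,C15
14,C16
15,C4
16,S17
17,C18
18,C19
19,C22
20,C23
21,O25
22,O24
23,C5
24,C6
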