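well,substrate,is_water
A1,water,1
A2,C01,0
A3,C02,0
A4,C03,0
A5,C04,0
A6,C05,0
A7,C06,0
A8,C07,0
A9,C08,0
A10,C09,0
A11,C10,0
A12,C11,0
B1,C12,0
B2,C13,0
B3,C14,0
B4,C15,0
B5,C16,0
B6,C17,0
B7,C18,0
B8,C19,0
B9,C20,0
B10,C21,0
B11,C22,0
B12,C23,0
C1,C24,0
C2,C25,0
C3,C26,0
C4,C27,0
C5,C28,0
C6,C29,0
C7,C30,0
C8,C31,0
C9,C32,0
C10,C33,0
C11,C34,0
C12,C35,0
D1,C36,0
D2,C37,0
D3,C38,0
D4,C39,0
D5,C40,0
D6,C41,0
D7,C42,0
D8,C43,0
D9,C44,0
D10,C45,0
D11,C46,0
D12,C47,0
E1,C48,0
E2,C49,0
E3,C50,0
E4,C51,0
E5,C52,0
E6,C53,0
E7,C54,0
E8,C55,0
E9,C56,0
E10,C57,0
E11,C58,0
E12,C59,0
F1,C60,0
F2,C61,0
F3,C62,0
F4,C63,0
F5,C64,0
F6,C65,0
F7,C66,0
F8,C67,0
F9,C68,0
F10,C69,0
F11,C70,0
F12,C71,0
G1,C72,0
G2,C73,0
G3,C74,0
G4,C75,0
G5,C76,0
G6,C77,0
G7,C78,0
G8,C79,0
G9,C80,0
G10,C81,0
G11,C82,0
G12,C83,0
H1,C84,0
H2,C85,0
H3,C86,0
H4,C87,0
H5,C88,0
H6,C89,0
H7,C90,0
H8,C91,0
H9,C92,0
H10,C93,0
H11,C94,0
H12,C95,0
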