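61 25 26 27 28 22 15 14 13 12 16 86 87 89 85 88 84 83 82 24
23 40 104 103 102 21 159 160 162 161 125 38 37 10 9 7 6 5 8 11
4 62 63 79 80 81 2 78 3 1 66 149 39 41 124 68 69 70 71 20
34 90 112 111 109 110 113 114 115 116 157 158 156 101 100 106 99 96 97 98
75 44 72 73 43 155 42 136 17 76 132 108 107 131 130 36 35 32 30 31
64 92 165 164 153 123 122 121 67 19 51 49 50 138 139 137 144 143 141 140
145 146 142 147 148 18 129 54 53 52 47 29 93 91 126 128 74 127 45 46
77 167 168 117 118 120 119 135 134 166 33 163 65 133 59 58 57 60 56 55
154 150 151 152 48 105 95 94 174 173 175 176 177 184 185 187 186 172 171 179
180 181 182 183 178 170 169 188 189 190 191 192 193
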