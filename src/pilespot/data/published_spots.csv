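type,pile_id,distances_m,day,localization
hot,A1,2.5;17.5;32.5,20,In the center
hot,A1,2.5;32.5,28,In the center
hot,A1,32.5,41,In the top left corner
hot,A2,2.5,25,In the center of pile
hot,A2,2.5,32,In the top left corner
hot,A2,17.5,47,In the top left corner
hot,B1,17.5,9,In the center of pile
hot,B1,2.5;17.5;32.5;47.5,16,In the center and left side
hot,B1,2.5;17.5;32.5;47.5,22,In the center and left side
hot,B1,2.5;17.5;32.5;47.5,31,In the center and left side
hot,B1,2.5;17.5;32.5;47.5,41,In the center and left side
hot,B1,17.5,57,In the left bottom corner
hot,B2,2.5;32.5;47.5,8,In the center and left side
hot,B2,32.5,16,In the left bottom corner
hot,B2,17.5;32.5;47.5,24,In the center and right side
hot,B2,32.5,43,Right down corner
hot,C1,32.5,28,In the center
hot,C2,17.5,9,On the right side
hot,C2,32.5,21,On the left side
hot,C2,17.5,35,On the left and right corner
cold,A1,2.5;17.5;32.5,20,In the left side in the bottom
cold,A1,2.5;32.5,28,In the bottom
cold,A2,2.5;17.5,17,In the bottom
cold,A2,2.5;17.5;32.5,25,In the bottom
cold,A2,2.5;17.5,38,In the bottom
cold,A2,2.5;17.5;32.5;47.5,57,In the bottom
cold,B1,32.5;47.5,1,In the bottom and in the center
cold,B2,2.5;17.5;32.5;47.5,1,In the bottom
cold,B2,2.5,43,In the bottom and in the center
cold,C1,2.5;17.5,28,left side; near to sidewalls and in the bottom
cold,C1,2.5;32.5;47.5,35,left side; near to sidewalls
cold,C1,2.5;32.5;47.5,42,Left and right side; near to sidewalls
cold,C2,2.5;17.5;32.5;47.5,1,In the bottom
cold,C2,32.5;47.5,28,In the bottom
cold,C2,2.5;32.5;47.5,35,In the bottom; left side; near to sidewalls
cold,C2,2.5;32.5;47.5,42,In the bottom; left side; near to sidewalls
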