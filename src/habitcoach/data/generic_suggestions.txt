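# Synthetic placeholder pool of 42 generic healthy-living suggestions for the
# control arm. The texts are stand-ins written for this package; only the pool
# size and the uniform-sampling mechanics matter to the engine.
Take the stairs instead of the elevator today.
Drink a glass of water before every meal.
Go for a 20-minute walk after lunch.
Swap one sugary drink for water or tea.
Add a serving of vegetables to dinner.
Stand up and stretch once every hour.
Park farther from the entrance and walk.
Eat a piece of fruit instead of a packaged snack.
Do 10 minutes of stretching before bed.
Get off the bus one stop early and walk.
Replace white bread with whole-grain bread.
Try a meat-free dinner once this week.
Take a short walk during a phone call.
Keep a bowl of fruit visible at home.
Cook dinner at home instead of eating out.
Do a set of bodyweight squats in the morning.
Choose grilled over fried food today.
Walk to a colleague's desk instead of emailing.
Portion snacks into a small bowl, not the bag.
Take a 10-minute walk before breakfast.
Eat slowly and stop when comfortably full.
Add a 15-minute bike ride to your day.
Choose a side salad instead of fries.
Try a new vegetable this week.
Do calf raises while waiting in line.
Skip dessert on weekdays.
Walk around the block after dinner.
Use a smaller plate for main meals.
Stretch your back and shoulders mid-afternoon.
Pack a healthy lunch the night before.
Take a walking meeting instead of sitting.
Limit second helpings at dinner.
Do 5 minutes of jumping jacks midday.
Choose water when eating out.
Add beans or lentils to one meal this week.
Walk briskly for the first 5 minutes of a walk.
Keep cut vegetables ready in the fridge.
Try the gym or a fitness class once this week.
Avoid eating in front of a screen.
Take a lap around your floor every two hours.
Choose fruit for dessert tonight.
End the day with a short relaxing walk.
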